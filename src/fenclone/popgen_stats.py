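"""Per-plot genetic-variation indices from codominant allele frequencies.

Conventions follow the widely used population-genetics summary software for
codominant data:

* ``Na``  — mean, over retained loci, of the number of alleles observed.
* ``Ne``  — mean of the effective number of alleles, ``1 / sum(p_i^2)``.
* ``Ho``  — mean observed heterozygosity (fraction of complete samples with
  two distinct alleles).
* ``He``  — mean *unbiased* expected heterozygosity,
  ``(2n / (2n - 1)) * (1 - sum(p_i^2))`` with ``n`` the number of complete
  samples at the locus.
* ``F``   — fixation index, averaged per locus as ``(He_l - Ho_l) / He_l``
  using the *biased* ``He_l = 1 - sum(p_i^2)``, over polymorphic loci only;
  undefined (None) when no locus is polymorphic.  ``F = 1`` exactly when
  allelic variation exists but no heterozygote was observed.

All indices are computed over every sampled ramet (not one ramet per genet)
by default; loci with no complete sample in a plot are skipped from that
plot's means.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict
from typing import Optional

from .io_formats import GenotypeTable, PlotEnvironment, ValidationError
from .clones import MLGAssignment, clones_per_plot, clonal_diversity

log = logging.getLogger("fenclone.popgen")


@dataclass
class LocusFrequencies:
    """Allele relative frequencies for one plot x locus cell."""
    plot_id: str
    locus: str
    freqs: dict[int, float]   # allele length -> relative frequency
    n: int                    # complete samples at this locus in this plot

    @property
    def empty(self) -> bool:
        return self.n == 0

    def sum_p2(self) -> float:
        return sum(p * p for p in self.freqs.values())


def allele_frequencies(
    table: GenotypeTable, plot_id: str, locus: str
) -> LocusFrequencies:
    """Tally allele copies (2 per complete sample) into relative frequencies."""
    counts: dict[int, int] = {}
    n = 0
    for s in table.samples_in_plot(plot_id):
        a, b = s.alleles[locus]
        if a is None or b is None:
            continue
        n += 1
        counts[a] = counts.get(a, 0) + 1
        counts[b] = counts.get(b, 0) + 1
    total = 2 * n
    freqs = {al: c / total for al, c in counts.items()} if n else {}
    return LocusFrequencies(plot_id, locus, freqs, n)


def plot_frequencies(table: GenotypeTable, plot_id: str) -> list[LocusFrequencies]:
    return [allele_frequencies(table, plot_id, l) for l in table.loci]


def na_per_plot(freqs: list[LocusFrequencies]) -> float:
    counts = [len(f.freqs) for f in freqs if not f.empty]
    return sum(counts) / len(counts)


def ne_per_plot(freqs: list[LocusFrequencies]) -> float:
    vals = []
    for f in freqs:
        if f.empty:
            log.warning("locus %s empty in plot %s; skipped", f.locus, f.plot_id)
            continue
        vals.append(1.0 / f.sum_p2())
    return sum(vals) / len(vals)


def ho_per_plot(table: GenotypeTable, plot_id: str) -> float:
    vals = []
    for locus in table.loci:
        n = n_het = 0
        for s in table.samples_in_plot(plot_id):
            a, b = s.alleles[locus]
            if a is None or b is None:
                continue
            n += 1
            if a != b:
                n_het += 1
        if n:
            vals.append(n_het / n)
    return sum(vals) / len(vals)


def uhe_per_plot(freqs: list[LocusFrequencies]) -> float:
    vals = []
    for f in freqs:
        if f.empty:
            continue
        two_n = 2 * f.n
        vals.append((two_n / (two_n - 1)) * (1.0 - f.sum_p2()))
    return sum(vals) / len(vals)


def fixation_index(
    table: GenotypeTable, freqs: list[LocusFrequencies], plot_id: str
) -> Optional[float]:
    vals = []
    for f in freqs:
        if f.empty:
            continue
        he_biased = 1.0 - f.sum_p2()
        if he_biased <= 0:
            continue
        n = n_het = 0
        for s in table.samples_in_plot(plot_id):
            a, b = s.alleles[f.locus]
            if a is None or b is None:
                continue
            n += 1
            if a != b:
                n_het += 1
        ho = n_het / n
        vals.append((he_biased - ho) / he_biased)
    if not vals:
        return None
    return sum(vals) / len(vals)


@dataclass
class PlotDiversity:
    """One row of the per-plot summary table."""
    plot_id: str
    elevation: float
    P: float
    K: float
    Ss: int
    Sf: int
    G: Optional[int]
    R: Optional[float]
    Na: float
    Ne: float
    Ho: float
    He: float
    F: Optional[float]

    def to_dict(self) -> dict:
        return asdict(self)


def summarize_plots(
    table: GenotypeTable,
    assignment: MLGAssignment,
    env: list[PlotEnvironment],
    n_for_r: str = "sampled",
) -> list[PlotDiversity]:
    """Assemble one PlotDiversity record per plot.

    ``n_for_r`` sets the N of the clonal-diversity denominator: ``"sampled"``
    uses all ramets collected in the plot (the sampling design's subplot
    count), ``"genotyped"`` only those with a complete multilocus genotype.
    """
    env_by_plot = {e.plot_id: e for e in env}
    missing_env = [p for p in table.plot_ids if p not in env_by_plot]
    if missing_env:
        raise ValidationError(f"plots missing from environment table: {missing_env}")
    g_map = clones_per_plot(assignment, table)
    out: list[PlotDiversity] = []
    for plot in table.plot_ids:
        e = env_by_plot[plot]
        samples = table.samples_in_plot(plot)
        if n_for_r == "sampled":
            n = len(samples)
        elif n_for_r == "genotyped":
            n = sum(1 for s in samples if s.sample_id in assignment.mlg_of_sample)
        else:
            raise ValueError(f"unknown n_for_r convention {n_for_r!r}")
        g = g_map[plot]
        r = clonal_diversity(g, n) if (g is not None and n >= 2) else None
        freqs = plot_frequencies(table, plot)
        out.append(PlotDiversity(
            plot_id=plot, elevation=e.elevation, P=e.P, K=e.K, Ss=e.Ss, Sf=e.Sf,
            G=g, R=r,
            Na=na_per_plot(freqs),
            Ne=ne_per_plot(freqs),
            Ho=ho_per_plot(table, plot),
            He=uhe_per_plot(freqs),
            F=fixation_index(table, freqs, plot),
        ))
    return out


def mean_row(diversity: list[PlotDiversity]) -> dict[str, float]:
    """Unweighted arithmetic mean of every numeric column across plots."""
    cols = ["elevation", "P", "K", "Ss", "Sf", "G", "R", "Na", "Ne", "Ho", "He", "F"]
    out = {}
    for c in cols:
        vals = [getattr(d, c) for d in diversity if getattr(d, c) is not None]
        out[c] = sum(vals) / len(vals) if vals else None
    return out
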