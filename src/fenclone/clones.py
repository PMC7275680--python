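"""Multilocus-genotype (clone) assignment and clonal diversity.

Samples with identical canonicalized allele pairs at every retained locus are
treated as ramets of the same clone (genet).  Matching is exact: no
genotypic-distance tolerance for somatic mutation or scoring error is applied.
Loci dominated by null alleles (missing calls) can be dropped beforehand with
:func:`filter_null_loci`; samples that still carry a missing call at a
retained locus are excluded from clone assignment (but remain available to
the allele-frequency statistics, which use per-locus sample counts).

Clonal diversity per plot follows the genotypic-richness convention
``R = (G - 1) / (N - 1)`` where ``G`` is the number of distinct multilocus
genotypes and ``N`` the number of ramets sampled: 0 for a monoclonal stand,
1 when every ramet is a distinct genet.
"""

from __future__ import annotations

import logging
import string
from dataclasses import dataclass, field

from .io_formats import GenotypeTable, ValidationError

log = logging.getLogger("fenclone.clones")


class PipelineError(RuntimeError):
    pass


def _mlg_label(i: int) -> str:
    """A, B, ..., Z, AA, AB, ... in order of first appearance."""
    letters = string.ascii_uppercase
    out = ""
    i += 1
    while i > 0:
        i, rem = divmod(i - 1, 26)
        out = letters[rem] + out
    return out


@dataclass
class LocusReport:
    locus: str
    n_missing: int          # samples with >=1 missing allele at this locus
    n_alleles_observed: int
    dropped: bool
    reason: str = ""


@dataclass
class LocusFilterReport:
    per_locus: list[LocusReport]
    threshold: float

    @property
    def dropped_loci(self) -> list[str]:
        return [r.locus for r in self.per_locus if r.dropped]


@dataclass
class MLGAssignment:
    mlg_of_sample: dict[str, str]            # sample_id -> label (A, B, ...)
    retained_loci: list[str]
    excluded_samples: list[tuple[str, str]] = field(default_factory=list)

    @property
    def n_mlgs(self) -> int:
        return len(set(self.mlg_of_sample.values()))


def filter_null_loci(
    table: GenotypeTable, max_missing_fraction: float
) -> tuple[GenotypeTable, LocusFilterReport]:
    """Drop loci whose fraction of samples with missing calls exceeds the
    threshold (strictly greater), mirroring the removal of a null-allele locus.
    """
    if not 0 <= max_missing_fraction <= 1:
        raise ValueError("max_missing_fraction must be in [0, 1]")
    n = len(table.samples)
    reports: list[LocusReport] = []
    keep: list[str] = []
    for locus in table.loci:
        n_missing = sum(1 for s in table.samples if None in s.alleles[locus])
        alleles = {
            v for s in table.samples for v in s.alleles[locus] if v is not None
        }
        frac = n_missing / n if n else 0.0
        dropped = frac > max_missing_fraction
        reason = (
            f"missing in {n_missing}/{n} samples "
            f"({frac:.3f} > {max_missing_fraction})" if dropped else ""
        )
        reports.append(LocusReport(locus, n_missing, len(alleles), dropped, reason))
        if not dropped:
            keep.append(locus)
        else:
            log.info("dropping locus %s: %s", locus, reason)
    if not keep:
        raise PipelineError("no informative loci: every locus exceeded the "
                            "missing-call threshold")
    return table.restrict_loci(keep), LocusFilterReport(reports, max_missing_fraction)


def assign_mlgs(table: GenotypeTable) -> MLGAssignment:
    """Group samples into multilocus genotypes by exact match over
    canonicalized allele pairs at all retained loci.

    Samples with any missing call at a retained locus are excluded with
    reason ``"incomplete genotype"``.  Labels run A, B, C, ... in order of
    first appearance in input order.
    """
    if not table.loci:
        raise PipelineError("no retained loci")
    signature_to_label: dict[tuple, str] = {}
    mlg_of_sample: dict[str, str] = {}
    excluded: list[tuple[str, str]] = []
    for s in table.samples:
        if not s.is_complete(table.loci):
            excluded.append((s.sample_id, "incomplete genotype"))
            continue
        sig = tuple(s.alleles[l] for l in table.loci)
        if sig not in signature_to_label:
            signature_to_label[sig] = _mlg_label(len(signature_to_label))
        mlg_of_sample[s.sample_id] = signature_to_label[sig]
    return MLGAssignment(mlg_of_sample, list(table.loci), excluded)


def clones_per_plot(
    assignment: MLGAssignment, table: GenotypeTable
) -> dict[str, int | None]:
    """Count distinct multilocus genotypes (G) among each plot's labeled
    samples; a plot with no labeled sample gets ``None`` with a warning."""
    out: dict[str, int | None] = {}
    for plot in table.plot_ids:
        labels = {
            assignment.mlg_of_sample[s.sample_id]
            for s in table.samples_in_plot(plot)
            if s.sample_id in assignment.mlg_of_sample
        }
        if not labels:
            log.warning("plot %s has no completely genotyped sample; G undefined",
                        plot)
            out[plot] = None
        else:
            out[plot] = len(labels)
    return out


def clonal_diversity(G: int, N: int) -> float:
    """Genotypic richness R = (G - 1) / (N - 1)."""
    if N < 2:
        raise ValueError("clonal diversity needs N >= 2 sampled ramets")
    if not 1 <= G <= N:
        raise ValidationError(f"clone count G={G} outside [1, N={N}]")
    return (G - 1) / (N - 1)


def mlg_plot_grid(assignment: MLGAssignment, table: GenotypeTable,
                  plot_id: str) -> str:
    """Text rendering of a plot's subplot sequence as MLG labels
    (``.`` marks an excluded sample)."""
    cells = []
    for s in sorted(table.samples_in_plot(plot_id), key=lambda s: s.subplot_index):
        cells.append(assignment.mlg_of_sample.get(s.sample_id, "."))
    return " ".join(cells)
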