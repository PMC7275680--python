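"""Readers and writers for the tabular artifacts of the fen-clonality pipeline.

Genotype tables are codominant microsatellite scores: for every sample and
locus an unordered pair of fragment lengths (base pairs).  Two dialects are
accepted: the GenAlEx codominant CSV layout (three header rows: a counts row,
a title/population row, and a column-labels row) and a flat headered CSV
(``sample,plot,subplot,LOCUS.1,LOCUS.2,...``).  The dialect is auto-detected
from the first cell of the first row (numeric -> GenAlEx).

A fragment length of 0 or an empty cell encodes a missing call (a null allele
or failed amplification); internally missing is ``None`` and on write it is
emitted as 0, following the GenAlEx convention.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

log = logging.getLogger("fenclone.io")

#: sentinel for a missing allele call (inside allele pairs it is ``None``)
MISSING = None

AllelePair = tuple[Optional[int], Optional[int]]


class FormatError(ValueError):
    """Structurally malformed input file."""


class ValidationError(ValueError):
    """Well-formed file whose content violates an invariant."""


def canonical_pair(a: Optional[int], b: Optional[int]) -> AllelePair:
    """Canonicalize an unordered codominant allele pair (missing sorts last)."""
    key = lambda v: (v is None, v)
    x, y = sorted((a, b), key=key)
    return (x, y)


@dataclass(frozen=True)
class SampleRecord:
    sample_id: str
    plot_id: str
    subplot_index: int
    alleles: dict[str, AllelePair] = field(hash=False)

    def n_missing(self) -> int:
        return sum(1 for p in self.alleles.values() for v in p if v is None)

    def is_complete(self, loci: Sequence[str]) -> bool:
        return all(None not in self.alleles[l] for l in loci)


@dataclass
class GenotypeTable:
    """Samples x loci table of codominant allele pairs (diploid)."""

    samples: list[SampleRecord]
    loci: list[str]
    ploidy: int = 2

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.ploidy != 2:
            raise ValidationError("only diploid tables are supported")
        seen_ids: set[str] = set()
        seen_pos: set[tuple[str, int]] = set()
        for s in self.samples:
            if s.sample_id in seen_ids:
                raise ValidationError(f"duplicate sample_id {s.sample_id!r}")
            seen_ids.add(s.sample_id)
            pos = (s.plot_id, s.subplot_index)
            if pos in seen_pos:
                raise ValidationError(f"duplicate (plot, subplot) {pos!r}")
            seen_pos.add(pos)
            if set(s.alleles) != set(self.loci):
                raise ValidationError(
                    f"sample {s.sample_id!r} loci do not match declared loci"
                )
            for locus, pair in s.alleles.items():
                for v in pair:
                    if v is not None and (not isinstance(v, int) or v <= 0):
                        raise ValidationError(
                            f"sample {s.sample_id!r} locus {locus!r}: fragment "
                            f"length must be a positive integer or missing, got {v!r}"
                        )

    @property
    def plot_ids(self) -> list[str]:
        out: list[str] = []
        for s in self.samples:
            if s.plot_id not in out:
                out.append(s.plot_id)
        return out

    def samples_in_plot(self, plot_id: str) -> list[SampleRecord]:
        return [s for s in self.samples if s.plot_id == plot_id]

    def n_missing_calls(self) -> int:
        return sum(s.n_missing() for s in self.samples)

    def restrict_loci(self, loci: Sequence[str]) -> "GenotypeTable":
        keep = [l for l in self.loci if l in set(loci)]
        samples = [
            SampleRecord(
                s.sample_id, s.plot_id, s.subplot_index,
                {l: s.alleles[l] for l in keep},
            )
            for s in self.samples
        ]
        return GenotypeTable(samples=samples, loci=keep)


@dataclass(frozen=True)
class PlotEnvironment:
    plot_id: str
    elevation: float  # m above sea level
    P: float          # mg per kg soil
    K: float          # mg per kg soil
    Ss: int           # total shoot count
    Sf: int           # flowering shoot count

    def __post_init__(self) -> None:
        for name in ("P", "K", "Ss", "Sf"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")


@dataclass(frozen=True)
class PlotCoordinates:
    plot_id: str
    x: float  # planar metres; used only through Euclidean distances
    y: float

    def __post_init__(self) -> None:
        import math

        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValidationError(f"non-finite coordinate for plot {self.plot_id!r}")


# ---------------------------------------------------------------------------
# genotype readers / writers

def _parse_allele(cell: str, where: str) -> Optional[int]:
    cell = cell.strip()
    if cell in ("", "0"):
        return None
    try:
        v = int(float(cell))
    except ValueError as e:
        raise FormatError(f"{where}: non-numeric allele {cell!r}") from e
    if v <= 0:
        return None
    return v


def read_genotypes(path: str | Path) -> GenotypeTable:
    """Read a codominant genotype table, auto-detecting the dialect.

    GenAlEx layout (first cell numeric): three header rows, then one row per
    sample ``sample_id, population, a1, a2, a1, a2, ...``; the population
    column is the plot id and subplot indices are assigned in file order
    within each plot.  Flat layout: header ``sample,plot,subplot`` followed
    by two columns per locus named ``LOCUS.1, LOCUS.2``.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        rows = [r for r in csv.reader(fh)]
    rows = [r for r in rows if any(c.strip() for c in r)]
    if not rows:
        raise FormatError(f"{path}: empty genotype file")
    first = rows[0][0].strip()
    try:
        float(first)
        genalex = True
    except ValueError:
        genalex = False
    table = _read_genalex(rows, path) if genalex else _read_flat(rows, path)
    log.info(
        "read %d samples, %d loci, %d missing calls from %s",
        len(table.samples), len(table.loci), table.n_missing_calls(), path,
    )
    return table


def _read_genalex(rows: list[list[str]], path: Path) -> GenotypeTable:
    if len(rows) < 4:
        raise FormatError(f"{path}: GenAlEx file needs 3 header rows + data")
    labels = rows[2]
    if len(labels) < 4 or (len(labels) - 2) % 2 != 0:
        raise FormatError(
            f"{path}: line 3: odd number of allele columns in GenAlEx header"
        )
    loci: list[str] = []
    for i in range(2, len(labels), 2):
        name = labels[i].strip()
        if not name:
            raise FormatError(f"{path}: line 3: blank locus name in column {i + 1}")
        loci.append(name)
    samples: list[SampleRecord] = []
    counter: dict[str, int] = {}
    for lineno, row in enumerate(rows[3:], start=4):
        if len(row) < 2 + 2 * len(loci):
            raise FormatError(f"{path}: line {lineno}: too few columns")
        sid, plot = row[0].strip(), row[1].strip()
        counter[plot] = counter.get(plot, 0) + 1
        alleles = {}
        for j, locus in enumerate(loci):
            a = _parse_allele(row[2 + 2 * j], f"{path}: line {lineno}")
            b = _parse_allele(row[3 + 2 * j], f"{path}: line {lineno}")
            alleles[locus] = canonical_pair(a, b)
        samples.append(SampleRecord(sid, plot, counter[plot], alleles))
    return GenotypeTable(samples=samples, loci=loci)


def _read_flat(rows: list[list[str]], path: Path) -> GenotypeTable:
    header = [c.strip() for c in rows[0]]
    if header[:3] != ["sample", "plot", "subplot"]:
        raise FormatError(
            f"{path}: line 1: flat dialect must start 'sample,plot,subplot'"
        )
    allele_cols = header[3:]
    if len(allele_cols) % 2 != 0:
        raise FormatError(f"{path}: line 1: odd number of allele columns")
    loci: list[str] = []
    for i in range(0, len(allele_cols), 2):
        a, b = allele_cols[i], allele_cols[i + 1]
        la, lb = a.rsplit(".", 1)[0], b.rsplit(".", 1)[0]
        if la != lb:
            raise FormatError(
                f"{path}: line 1: columns {a!r}/{b!r} are not a locus pair"
            )
        loci.append(la)
    samples: list[SampleRecord] = []
    for lineno, row in enumerate(rows[1:], start=2):
        if len(row) != len(header):
            raise FormatError(f"{path}: line {lineno}: wrong column count")
        sid, plot = row[0].strip(), row[1].strip()
        try:
            sub = int(row[2])
        except ValueError as e:
            raise FormatError(f"{path}: line {lineno}: bad subplot index") from e
        alleles = {}
        for j, locus in enumerate(loci):
            a = _parse_allele(row[3 + 2 * j], f"{path}: line {lineno}")
            b = _parse_allele(row[4 + 2 * j], f"{path}: line {lineno}")
            alleles[locus] = canonical_pair(a, b)
        samples.append(SampleRecord(sid, plot, sub, alleles))
    return GenotypeTable(samples=samples, loci=loci)


def write_genotypes(table: GenotypeTable, path: str | Path) -> None:
    """Write a genotype table in the flat dialect (missing as 0)."""
    path = Path(path)
    header = ["sample", "plot", "subplot"]
    for locus in table.loci:
        header += [f"{locus}.1", f"{locus}.2"]
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(header)
        for s in table.samples:
            row: list[object] = [s.sample_id, s.plot_id, s.subplot_index]
            for locus in table.loci:
                a, b = s.alleles[locus]
                row += [a or 0, b or 0]
            w.writerow(row)


# ---------------------------------------------------------------------------
# environment / coordinates

_ENV_COLS = ["plot_id", "elevation", "P", "K", "Ss", "Sf"]
_COORD_COLS = ["plot_id", "x", "y"]


def _read_table(path: str | Path, required: list[str]) -> list[dict[str, str]]:
    path = Path(path)
    with path.open(newline="") as fh:
        sample = fh.read(4096)
        fh.seek(0)
        first_line = sample.splitlines()[0] if sample else ""
        delim = "\t" if "\t" in first_line else ","
        reader = csv.DictReader(fh, delimiter=delim)
        rows = list(reader)
    if not rows:
        raise ValidationError(f"{path}: empty table")
    missing = [c for c in required if c not in (rows[0].keys())]
    if missing:
        raise ValidationError(f"{path}: missing column(s) {missing}")
    return rows


def read_environment(path: str | Path) -> list[PlotEnvironment]:
    rows = _read_table(path, _ENV_COLS)
    out, seen = [], set()
    for i, r in enumerate(rows, start=2):
        pid = r["plot_id"].strip()
        if pid in seen:
            raise ValidationError(f"{path}: duplicate plot_id {pid!r} (line {i})")
        seen.add(pid)
        try:
            out.append(PlotEnvironment(
                pid, float(r["elevation"]), float(r["P"]), float(r["K"]),
                int(float(r["Ss"])), int(float(r["Sf"])),
            ))
        except ValueError as e:
            raise ValidationError(f"{path}: line {i}: non-numeric cell") from e
    return out


def read_coordinates(path: str | Path) -> list[PlotCoordinates]:
    rows = _read_table(path, _COORD_COLS)
    out, seen, pts = [], set(), set()
    for i, r in enumerate(rows, start=2):
        pid = r["plot_id"].strip()
        if pid in seen:
            raise ValidationError(f"{path}: duplicate plot_id {pid!r} (line {i})")
        seen.add(pid)
        try:
            x, y = float(r["x"]), float(r["y"])
        except ValueError as e:
            raise ValidationError(f"{path}: line {i}: non-numeric cell") from e
        if (x, y) in pts:
            raise ValidationError(f"{path}: line {i}: coincident plots at ({x}, {y})")
        pts.add((x, y))
        out.append(PlotCoordinates(pid, x, y))
    return out


def write_environment(env: Iterable[PlotEnvironment], path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_ENV_COLS)
        for e in env:
            w.writerow([e.plot_id, e.elevation, e.P, e.K, e.Ss, e.Sf])


def write_coordinates(coords: Iterable[PlotCoordinates], path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_COORD_COLS)
        for c in coords:
            w.writerow([c.plot_id, c.x, c.y])


# ---------------------------------------------------------------------------
# result writers (per-plot summary table + regression blocks)

#: column order of the per-plot summary TSV
DIVERSITY_COLS = ["Pl.", "El.", "P", "K", "Ss", "Sf",
                  "G", "R", "Na", "Ne", "Ho", "He", "F"]
REGRESSION_COLS = ["Model Parameter", "MPV", "ESS", "HDI_L", "HDI_U",
                   "PDist", "class"]


def _fmt(v, decimals: int = 2) -> str:
    if v is None:
        return "NA"
    if isinstance(v, float):
        return f"{v:.{decimals}f}"
    return str(v)


def write_results(diversity, regressions, out_dir: str | Path) -> dict[str, Path]:
    """Write the per-plot summary TSV (+ mean row), one regression TSV per
    dependent variable, and a full-precision JSON of everything.

    ``diversity`` is a list of PlotDiversity (see :mod:`fenclone.popgen_stats`),
    ``regressions`` a list of RegressionSummary (see :mod:`fenclone.robust_bayes`).
    Returns a name -> path map of the files written.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    div_path = out_dir / "plot_diversity.tsv"
    with div_path.open("w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(DIVERSITY_COLS)
        numeric = ["elevation", "P", "K", "Ss", "Sf",
                   "G", "R", "Na", "Ne", "Ho", "He", "F"]
        decimals = {"elevation": 1, "P": 1, "K": 1, "Ss": 0, "Sf": 0, "G": 0}
        for d in diversity:
            w.writerow([d.plot_id] + [
                _fmt(getattr(d, c), decimals.get(c, 2)) for c in numeric
            ])
        means = []
        for c in numeric:
            vals = [getattr(d, c) for d in diversity if getattr(d, c) is not None]
            means.append(_fmt(sum(vals) / len(vals), decimals.get(c, 2))
                         if vals else "NA")
        w.writerow(["mean"] + means)
    written["plot_diversity"] = div_path

    if regressions:
        for summ in regressions:
            p = out_dir / f"regression_{summ.response}.tsv"
            with p.open("w", newline="") as fh:
                w = csv.writer(fh, delimiter="\t")
                w.writerow(REGRESSION_COLS)
                for row in summ.rows:
                    w.writerow([
                        row.parameter, _fmt(row.mpv), f"{row.ess:.0f}",
                        _fmt(row.hdi_low), _fmt(row.hdi_high),
                        _fmt(row.pdist) if row.pdist is not None else "-",
                        row.credibility or "-",
                    ])
            written[f"regression_{summ.response}"] = p
    else:
        log.warning("no regression summaries supplied; regression tables omitted")

    json_path = out_dir / "results.json"
    payload = {
        "diversity": [d.to_dict() for d in diversity],
        "regressions": [r.to_dict() for r in regressions],
    }
    with json_path.open("w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")
    written["json"] = json_path
    return written


def read_results_json(path: str | Path) -> dict:
    with Path(path).open() as fh:
        return json.load(fh)
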