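"""End-to-end orchestration: read -> filter -> clones -> diversity ->
detrend -> regress -> report.

Every run writes its artifacts plus a MANIFEST.json naming each produced
file with a content hash, the effective configuration, and any collected
warnings (ESS shortfalls, empty MEM selections, fallbacks).  With
``strict=True`` warnings are promoted to errors.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from . import clones, io_formats, mem_spatial, popgen_stats, robust_bayes

log = logging.getLogger("fenclone.pipeline")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    genotypes: Optional[str] = None
    environment: Optional[str] = None
    coordinates: Optional[str] = None
    out_dir: str = "fenclone_out"
    seed: int = 0
    null_locus_threshold: float = 0.03
    n_for_r: str = "sampled"           # or "genotyped"
    mem_alpha: float = 0.05
    mem_nperm: int = 999
    mem_seed: int = 20200603
    mem_positive_only: bool = True
    hdi_mass: float = 0.90
    schedule: robust_bayes.Schedule = field(default_factory=robust_bayes.Schedule)
    priors: robust_bayes.Priors = field(default_factory=robust_bayes.Priors)
    strict: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with Path(path).open() as fh:
            raw = yaml.safe_load(fh) or {}
        sched = robust_bayes.Schedule(**raw.pop("schedule", {}))
        priors = robust_bayes.Priors(**raw.pop("priors", {}))
        return cls(schedule=sched, priors=priors, **raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with path.open("rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def compute_diversity(cfg: PipelineConfig):
    """Stages read -> filter -> clones -> per-plot indices."""
    try:
        table = io_formats.read_genotypes(cfg.genotypes)
        env = io_formats.read_environment(cfg.environment)
    except Exception as e:
        raise StageError("read", e) from e
    try:
        table, filter_report = clones.filter_null_loci(
            table, cfg.null_locus_threshold)
        assignment = clones.assign_mlgs(table)
        diversity = popgen_stats.summarize_plots(table, assignment, env,
                                                 n_for_r=cfg.n_for_r)
    except Exception as e:
        raise StageError("diversity", e) from e
    return table, assignment, filter_report, diversity


def detrend_diversity(cfg: PipelineConfig, diversity, coords):
    """MEM selection and spatial detrending of the dependent variables.

    Returns (detrended map, diagnostics).  Variables undefined in some plot
    are left out of the map (the regression stage then uses raw values)."""
    warnings: list[str] = []
    dist = mem_spatial.euclidean_distances(coords)
    candidates = mem_spatial.candidate_weights(dist)
    variables = {}
    for name in robust_bayes.DEPENDENT_VARIABLES:
        vals = [getattr(d, name) for d in diversity]
        if any(v is None for v in vals):
            warnings.append(f"{name} undefined in some plot; not detrended")
            continue
        v = np.asarray(vals, dtype=float)
        if v.std(ddof=1) == 0:
            warnings.append(f"{name} constant; not detrended")
            continue
        variables[name] = v
    if not variables:
        return {}, {"warnings": warnings, "candidates": []}
    Y = np.column_stack(list(variables.values()))
    swm, basis, diag = mem_spatial.select_swm(Y, candidates,
                                              nperm=cfg.mem_nperm,
                                              seed=cfg.mem_seed)
    detrended: dict[str, np.ndarray] = {}
    selections: dict[str, dict] = {}
    for name, v in variables.items():
        sel, pvals = mem_spatial.significant_mems(
            v, basis, alpha=cfg.mem_alpha, nperm=cfg.mem_nperm,
            seed=cfg.mem_seed, positive_only=cfg.mem_positive_only)
        res = mem_spatial.detrend(v, basis, sel, response=name, p_values=pvals)
        detrended[name] = res.residuals
        selections[name] = {"selected": sel,
                            "p_values": {str(k): p for k, p in pvals.items()},
                            "r2": res.r2, "adj_r2": res.adj_r2}
        if not sel:
            warnings.append(f"no significant spatial predictor for {name}; "
                            "passthrough")
    diagnostics = {"chosen_swm": swm.descriptor, "candidates": diag,
                   "selections": selections, "warnings": warnings}
    return detrended, diagnostics


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run the whole analysis; returns a manifest dict (also written to
    ``out_dir/MANIFEST.json``)."""
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fh = logging.FileHandler(out_dir / "run.log", mode="w")
    fh.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logging.getLogger("fenclone").addHandler(fh)
    warnings: list[str] = []
    files: dict[str, Path] = {}
    complete = False
    error: Optional[str] = None
    try:
        table, assignment, filter_report, diversity = compute_diversity(cfg)

        mlg_path = out_dir / "mlg_assignment.tsv"
        with mlg_path.open("w") as out:
            out.write("sample\tplot\tsubplot\tmlg\n")
            for s in table.samples:
                label = assignment.mlg_of_sample.get(s.sample_id, "NA")
                out.write(f"{s.sample_id}\t{s.plot_id}\t{s.subplot_index}\t"
                          f"{label}\n")
        files["mlg_assignment"] = mlg_path

        detrended: dict[str, np.ndarray] = {}
        if cfg.coordinates:
            try:
                coords = io_formats.read_coordinates(cfg.coordinates)
                detrended, diag = detrend_diversity(cfg, diversity, coords)
                warnings.extend(diag.get("warnings", []))
                mem_path = out_dir / "mem_diagnostics.json"
                with mem_path.open("w") as out:
                    json.dump(diag, out, indent=1, sort_keys=True)
                    out.write("\n")
                files["mem_diagnostics"] = mem_path
            except Exception as e:
                raise StageError("detrend", e) from e
        else:
            warnings.append("no coordinate file; spatial detrending skipped")

        try:
            regressions = robust_bayes.run_all_regressions(
                diversity, detrended or None, seed=cfg.seed,
                schedule=cfg.schedule, priors=cfg.priors, mass=cfg.hdi_mass)
        except Exception as e:
            raise StageError("regress", e) from e
        for summ in regressions:
            warnings.extend(summ.warnings)

        files.update(io_formats.write_results(diversity, regressions, out_dir))
        complete = True
    except StageError as e:
        error = str(e)
        raise
    finally:
        logging.getLogger("fenclone").removeHandler(fh)
        fh.close()
        files["run_log"] = out_dir / "run.log"
        manifest = {
            "complete": complete,
            "error": error,
            "config": cfg.to_dict(),
            "warnings": warnings,
            "files": {k: {"path": str(p), "sha256": _sha256(p)}
                      for k, p in files.items()},
        }
        with (out_dir / "MANIFEST.json").open("w") as out:
            json.dump(manifest, out, indent=1, sort_keys=True)
            out.write("\n")

    if cfg.strict and warnings:
        raise StageError("strict", RuntimeError("; ".join(warnings)))
    return manifest
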