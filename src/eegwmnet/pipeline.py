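"""Configured, logged, resumable orchestration of the full analysis.

Stages: simulate -> preprocess -> connect -> graph -> stats.  Intermediate
artifacts are files (EDF, CSV, JSON), not in-memory handoffs, so each
stage is independently runnable and the run is resumable and auditable.
Every random draw descends from the single configured seed, so a run is
reproducible byte-for-byte for text outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .connectivity import band_centers, read_matrix_csv, wpli_band, write_matrix_csv
from .graph import (
    betweenness,
    clustering,
    communities,
    hubness,
    path_metrics,
    small_world,
    threshold_proportional,
    write_tidy_metrics,
)
from .preproc import RejectionCriteria, log_to_rows, reject_epochs, write_rejection_csv
from .stats import fit_age_gam, screen_correlations
from .synth import (
    CONDITIONS,
    DOMAINS,
    PROFILES,
    SubjectRecord,
    draw_epoch_count,
    inject_artifacts,
    read_cohort_csv,
    read_epochs_edf,
    simulate_cohort,
    simulate_epochs,
    write_cohort_csv,
    write_epochs_edf,
)

logger = logging.getLogger(__name__)

ALL_BANDS = ("delta", "theta", "alpha", "beta", "gamma")
GLOBAL_METRICS = ("cpl", "geff", "cc", "modularity_q", "gamma", "lambda", "sigma")
METRIC_FAMILIES = {
    "cpl": "integration", "geff": "integration",
    "cc": "segregation", "modularity_q": "segregation",
    "gamma": "global", "lambda": "global", "sigma": "global",
}


@dataclass
class RunConfig:
    seed: int = 1
    n_subjects: int = 39
    age_min: float = 20.0
    age_max: float = 81.0
    profile: str = "default"           # name in synth.PROFILES
    conditions: tuple[str, ...] = CONDITIONS
    epoch_count: int = 0               # 0 -> draw per subject (truncated normal)
    cognition_noise_scale: float = 1.0
    artifact_fraction: float = 0.05    # fraction of epochs contaminated
    max_abs_amplitude: float = 70.0
    max_step: float = 50.0
    max_diff_200ms: float = 50.0
    min_activity_100ms: float = 0.5
    threshold: float = 0.55
    bands: tuple[str, ...] = ALL_BANDS
    sw_convention: str = "as_printed"
    k_cognitive: int = 10
    k_graph: int = 12
    fdr_q: float = 0.05
    min_abs_r: float = 0.400
    hub_threshold: float = 0.3
    save_spectra: bool = False
    outdir: str = "eegwmnet_run"

    def criteria(self) -> RejectionCriteria:
        return RejectionCriteria(
            max_abs_amplitude=self.max_abs_amplitude,
            max_step=self.max_step,
            max_diff_200ms=self.max_diff_200ms,
            min_activity_100ms=self.min_activity_100ms,
        )

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["conditions"] = ",".join(self.conditions)
        d["bands"] = ",".join(self.bands)
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(d, fh, sort_keys=True, default_flow_style=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            d = yaml.safe_load(fh)
        d["conditions"] = tuple(d["conditions"].split(","))
        d["bands"] = tuple(d["bands"].split(","))
        return cls(**d)

    def digest(self) -> str:
        d = asdict(self)
        d["conditions"] = list(self.conditions)
        d["bands"] = list(self.bands)
        return hashlib.sha256(
            json.dumps(d, sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class RunManifest:
    config_hash: str
    version: str
    stage_seconds: dict[str, float] = field(default_factory=dict)
    checksums: dict[str, str] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=1)


def _file_sha(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _subject_seed(config_seed: int, subject_idx: int, cond_idx: int, salt: int = 0):
    return np.random.SeedSequence(
        entropy=(config_seed, subject_idx, cond_idx, salt)
    )


def _edf_path(outdir: Path, subdir: str, subject_id: str, condition: str) -> Path:
    return outdir / subdir / f"{subject_id}_{condition}.edf"


# --------------------------------------------------------------------------
# Stages
# --------------------------------------------------------------------------


def stage_simulate(config: RunConfig) -> None:
    """Cohort CSV plus one raw EDF (+ JSON sidecar) per subject/condition."""
    outdir = Path(config.outdir)
    (outdir / "edf").mkdir(parents=True, exist_ok=True)
    profile = PROFILES[config.profile]
    cohort = simulate_cohort(
        n_subjects=config.n_subjects,
        age_min=config.age_min,
        age_max=config.age_max,
        seed=config.seed,
        noise_scale=config.cognition_noise_scale,
    )
    write_cohort_csv(cohort, outdir / "cohort.csv")
    for si, subject in enumerate(cohort):
        for ci, cond in enumerate(config.conditions):
            ss = _subject_seed(config.seed, si, ci)
            child = ss.generate_state(4)
            rng = np.random.default_rng(ss)
            n_epochs = config.epoch_count or draw_epoch_count(rng)
            epochs = simulate_epochs(
                subject, cond, profile, n_epochs, seed=int(child[0] % 2**31)
            )
            n_bad = int(round(config.artifact_fraction * n_epochs))
            if n_bad:
                bad = rng.choice(n_epochs, size=n_bad, replace=False)
                kinds = ["amplitude", "step", "flatline"]
                mags = {"amplitude": 120.0, "step": 250.0, "flatline": 0.4}
                for b_i, b in enumerate(bad):
                    kind = kinds[b_i % 3]
                    epochs = inject_artifacts(
                        epochs, kind, [int(b)], mags[kind],
                        seed=int(child[1] % 2**31) + b_i,
                    )
            write_epochs_edf(
                epochs, _edf_path(outdir, "edf", subject.subject_id, cond),
                subject=subject, profile=profile,
            )
    logger.info("simulate: %d subjects x %d conditions written",
                len(cohort), len(config.conditions))


def stage_preprocess(config: RunConfig) -> None:
    """Artifact rejection per subject/condition; cleaned EDFs plus report."""
    outdir = Path(config.outdir)
    (outdir / "clean").mkdir(parents=True, exist_ok=True)
    cohort = read_cohort_csv(outdir / "cohort.csv")
    criteria = config.criteria()
    rows = []
    for subject in cohort:
        for cond in config.conditions:
            epochs = read_epochs_edf(_edf_path(outdir, "edf", subject.subject_id, cond))
            kept, log = reject_epochs(epochs, criteria)
            rows.extend(log_to_rows(subject.subject_id, cond, log))
            write_epochs_edf(kept, _edf_path(outdir, "clean", subject.subject_id, cond))
    write_rejection_csv(outdir / "rejection_report.csv", rows)


def stage_connect(config: RunConfig) -> None:
    """Band wPLI matrices (optionally the full 48-frequency spectrum)."""
    outdir = Path(config.outdir)
    (outdir / "conn").mkdir(parents=True, exist_ok=True)
    cohort = read_cohort_csv(outdir / "cohort.csv")
    manifest = []
    for subject in cohort:
        for cond in config.conditions:
            epochs = read_epochs_edf(_edf_path(outdir, "clean", subject.subject_id, cond))
            for band in config.bands:
                bm = wpli_band(epochs, band)
                path = outdir / "conn" / f"{subject.subject_id}_{cond}_{band}.csv"
                write_matrix_csv(path, bm.matrix, bm.labels)
                manifest.append(
                    {"subject_id": subject.subject_id, "condition": cond,
                     "band": band, "centers": list(band_centers(band)),
                     "bandwidth": 1.0, "n_epochs": int(epochs.n_epochs),
                     "file": path.name}
                )
    with open(outdir / "conn" / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1)


def stage_graph(config: RunConfig) -> None:
    """Threshold each band matrix and compute all graph metrics (tidy CSV)."""
    outdir = Path(config.outdir)
    cohort = read_cohort_csv(outdir / "cohort.csv")
    rows = []
    for si, subject in enumerate(cohort):
        for ci, cond in enumerate(config.conditions):
            for band in config.bands:
                path = outdir / "conn" / f"{subject.subject_id}_{cond}_{band}.csv"
                matrix, labels = read_matrix_csv(path)
                tg = threshold_proportional(matrix, config.threshold, labels=labels)
                louvain_seed = int(
                    _subject_seed(config.seed, si, ci, salt=97).generate_state(1)[0]
                    % 2**31
                )
                rows.extend(
                    graph_metric_rows(
                        tg, subject.subject_id, cond, band,
                        louvain_seed=louvain_seed,
                        sw_convention=config.sw_convention,
                        hub_threshold=config.hub_threshold,
                    )
                )
    write_tidy_metrics(outdir / "metrics.csv", rows)


def graph_metric_rows(
    tg,
    subject_id: str,
    condition: str,
    band: str,
    louvain_seed: int,
    sw_convention: str = "as_printed",
    hub_threshold: float = 0.3,
) -> list[dict]:
    """All global and nodewise metrics of one thresholded graph, tidy rows."""
    pm = path_metrics(tg)
    cc_node, cc_mean = clustering(tg)
    bc = betweenness(tg)
    module_id, q, module_z = communities(tg, seed=louvain_seed)
    part, hub = hubness(tg, module_id, threshold=hub_threshold)
    sw = small_world(
        tg, convention=sw_convention,
        seed=louvain_seed if sw_convention == "watts_strogatz" else None,
    )
    base = {"subject_id": subject_id, "condition": condition, "band": band}
    rows = [
        {**base, "scope": "global", "node": "", "metric": m, "value": v}
        for m, v in [
            ("cpl", pm.cpl), ("geff", pm.global_efficiency), ("cc", cc_mean),
            ("modularity_q", q), ("gamma", sw.gamma), ("lambda", sw.lam),
            ("sigma", sw.sigma),
        ]
    ]
    for i, lab in enumerate(tg.labels):
        for m, v in [
            ("bc", bc[i]), ("cc", cc_node[i]), ("module_z", module_z[i]),
            ("participation", part[i]), ("hub_flag", float(hub[i])),
        ]:
            rows.append({**base, "scope": "node", "node": lab, "metric": m, "value": v})
    return rows


def stage_stats(config: RunConfig) -> list[str]:
    """Age GAMs (Table-2-shaped CSV) and the partial-correlation screen."""
    outdir = Path(config.outdir)
    cohort = read_cohort_csv(outdir / "cohort.csv")
    metrics = pd.read_csv(outdir / "metrics.csv")
    warnings: list[str] = []
    ages = np.array([s.age for s in cohort])
    order = {s.subject_id: i for i, s in enumerate(cohort)}

    behavioural = behavioural_frame(cohort)
    table1(behavioural, outdir / "table1.csv")

    gam_rows = []
    gam_pvalues: dict[str, float] = {}
    pairs = []

    def run_gam(name, values, k):
        if len(values) < k:
            msg = f"stats: n={len(values)} < k={k}; GAM skipped for {name}"
            if not any("GAM skipped" in w for w in warnings):
                logger.warning(msg)
            warnings.append(msg)
            return None
        try:
            return fit_age_gam(np.asarray(values), ages, k=k, outcome=name)
        except ValueError as exc:
            warnings.append(f"stats: GAM failed for {name}: {exc}")
            return None

    # behavioural / cognitive outcomes, basis order k_cognitive
    for col in behavioural.columns:
        if col in ("subject_id", "age"):
            continue
        fit = run_gam(col, behavioural[col].to_numpy(), config.k_cognitive)
        if fit is not None:
            gam_rows.append(gam_row(fit))

    # global graph metrics, basis order k_graph
    g = metrics[metrics.scope == "global"]
    for (cond, band, metric), sub in g.groupby(["condition", "band", "metric"]):
        sub = sub.copy()
        sub["order"] = sub.subject_id.map(order)
        sub = sub.sort_values("order")
        if len(sub) != len(cohort):
            warnings.append(f"stats: incomplete metric {metric} {cond}/{band}")
            continue
        name = f"{cond}:{band}:{metric}"
        fit = run_gam(name, sub.value.to_numpy(), config.k_graph)
        if fit is not None:
            gam_rows.append(gam_row(fit))
            gam_pvalues[name] = fit.p_smooth
            family = METRIC_FAMILIES.get(metric, "global")
            for score in behavioural.columns:
                if score in ("subject_id", "age"):
                    continue
                if score.startswith(("accuracy_", "rt_")) and not score.endswith(cond):
                    continue
                pairs.append(
                    (name, sub.value.to_numpy(), score,
                     behavioural[score].to_numpy(), family)
                )

    pd.DataFrame(
        gam_rows,
        columns=["outcome", "n", "k", "intercept_estimate", "intercept_se",
                 "intercept_t", "intercept_p", "edf", "ref_df", "f_value",
                 "p_value", "method"],
    ).to_csv(outdir / "gam_table.csv", index=False)

    screen = screen_correlations(
        pairs, ages, min_abs_r=config.min_abs_r, q=config.fdr_q,
        gam_pvalues=gam_pvalues,
    )
    screen.to_csv(outdir / "correlations.csv", index=False)
    return warnings


def gam_row(fit) -> dict:
    return {
        "outcome": fit.outcome, "n": fit.n, "k": fit.k,
        "intercept_estimate": fit.intercept_estimate,
        "intercept_se": fit.intercept_se, "intercept_t": fit.intercept_t,
        "intercept_p": fit.intercept_p, "edf": fit.edf, "ref_df": fit.ref_df,
        "f_value": fit.f_stat, "p_value": fit.p_smooth, "method": fit.method,
    }


def behavioural_frame(cohort: list[SubjectRecord]) -> pd.DataFrame:
    rows = []
    for s in cohort:
        row = {"subject_id": s.subject_id, "age": s.age, "mmse": s.mmse, "bdi": s.bdi}
        row.update({d: s.domain_scores[d] for d in DOMAINS})
        row.update({f"accuracy_{c}": s.accuracy[c] for c in s.accuracy})
        row.update({f"rt_{c}": s.rt[c] for c in s.rt})
        rows.append(row)
    return pd.DataFrame(rows)


def table1(behavioural: pd.DataFrame, path) -> None:
    """Demographics-style summary: mean (sd) and median per outcome."""
    rows = []
    for col in behavioural.columns:
        if col == "subject_id":
            continue
        v = behavioural[col].to_numpy()
        rows.append(
            {"outcome": col, "mean": float(np.mean(v)), "sd": float(np.std(v, ddof=1)),
             "median": float(np.median(v))}
        )
    pd.DataFrame(rows).to_csv(path, index=False)


STAGES = ("simulate", "preprocess", "connect", "graph", "stats")


def run_pipeline(config: RunConfig) -> RunManifest:
    """Run every stage in order; returns the manifest (also written to disk)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")
    manifest = RunManifest(config_hash=config.digest(), version=__version__)
    stage_fns = {
        "simulate": stage_simulate,
        "preprocess": stage_preprocess,
        "connect": stage_connect,
        "graph": stage_graph,
        "stats": stage_stats,
    }
    for name in STAGES:
        t0 = time.perf_counter()
        try:
            result = stage_fns[name](config)
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        if isinstance(result, list):
            manifest.warnings.extend(result)
        manifest.stage_seconds[name] = round(time.perf_counter() - t0, 3)
        logger.info("stage %s done in %.1fs", name, manifest.stage_seconds[name])
    for f in sorted(outdir.rglob("*.csv")):
        manifest.checksums[str(f.relative_to(outdir))] = _file_sha(f)
    manifest.save(outdir / "manifest.json")
    return manifest
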