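"""End-to-end orchestration: seeded runs, artifact layout and reporting.

A pipeline run walks protocol -> simulated t-maps -> normalization ->
similarity matrices -> group statistics, persisting every stage under an
output directory::

    out/
      config.yaml
      protocol/sub-XX_run-YY_events.tsv
      tmaps/sub-XX_desc-ROI_tmaps.csv          (run-normalized)
      matrices/sub-XX_desc-ROI_KIND.csv
      stats/{deltas,coding_tests,regressions,surrogate_tests,trimmed_tests}.csv
      log.json

Per-stage seeds are derived from the master seed by hashing the stage name
(CRC-32) into a :class:`numpy.random.SeedSequence`, so any stage can be
re-run in isolation and reproduce its part of a pipeline run.

The default per-ROI amplitudes plant the study's qualitative dissociation:
item (key) and position coding in the motor cortices, boundary-dominated
position coding in M1 and parahippocampus, and domain-general item-position
coding in hippocampus and perirhinal cortex.
"""

from __future__ import annotations

import dataclasses
import json
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import glm, protocol, rsa, simulate, stats
from .simulate import CodingAmplitudes

ROI_NAMES = ("M1", "PMC", "PER", "PHC", "HC")

#: dependent kind -> its random-condition predictors for attribution
ATTRIBUTION_MODELS = {
    "SQ_MOT": ["RD_KEY", "RD_POS"],
    "SQ_OBJ": ["RD_OBJ", "RD_POS"],
    "SQ_ACROSS": ["RD_ITEM", "RD_POS"],
}


def default_roi_amplitudes() -> dict[str, CodingAmplitudes]:
    """Qualitative coding profile of the five ROIs (see module docstring)."""
    return {
        # M1/PHC: position coding carried by the boundary pattern only, so
        # it vanishes once the edge positions are trimmed; PMC: genuine
        # position coding that survives trimming; PER/HC: domain-general
        # item-position coding without item or position coding.
        "M1": CodingAmplitudes(a_itempos=0.3, a_key=0.8, a_obj=0.0,
                               a_pos=0.0, a_boundary=0.6),
        "PMC": CodingAmplitudes(a_itempos=0.3, a_key=0.6, a_obj=0.0,
                                a_pos=0.6, a_boundary=0.2),
        "PER": CodingAmplitudes(a_itempos=0.4, a_key=0.0, a_obj=0.0,
                                a_pos=0.0, a_boundary=0.0),
        "PHC": CodingAmplitudes(a_itempos=0.25, a_key=0.0, a_obj=0.0,
                                a_pos=0.0, a_boundary=0.6),
        "HC": CodingAmplitudes(a_itempos=0.5, a_key=0.0, a_obj=0.0,
                               a_pos=0.0, a_boundary=0.0),
    }


@dataclass
class PipelineConfig:
    """Everything a run needs; ``seed`` is mandatory."""

    seed: int
    n_subjects: int = 30
    n_voxels: int = 100
    rois: dict[str, CodingAmplitudes] = field(default_factory=default_roi_amplitudes)
    correction: str = "bonferroni"
    n_perm: int = 1000
    iterations: str = "exhaustive"   # or "sampled:N"
    exclude_learned: bool = True

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name, amps in self.rois.items():
            if not isinstance(amps, CodingAmplitudes):
                self.rois[name] = CodingAmplitudes(**amps)

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        d.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**d)


def stage_seed(master_seed: int, stage: str) -> np.random.SeedSequence:
    """Derive a stage's seed: SeedSequence([master, crc32(stage)])."""
    return np.random.SeedSequence([master_seed, zlib.crc32(stage.encode())])


def _stage_int_seed(master_seed: int, stage: str) -> int:
    return int(stage_seed(master_seed, stage).generate_state(1)[0] & 0x7FFFFFFF)


def _splits_for(config: PipelineConfig, rng: np.random.Generator):
    all_splits = rsa.enumerate_splits()
    if config.iterations == "exhaustive":
        return all_splits
    if config.iterations.startswith("sampled:"):
        n = int(config.iterations.split(":")[1])
        idx = rng.choice(len(all_splits), size=n, replace=False)
        return [all_splits[i] for i in sorted(idx)]
    raise ValueError(f"unknown iteration scheme {config.iterations!r}")


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_protocol(config: PipelineConfig, outdir: Path) -> list:
    subjects = protocol.build_full_protocol(
        config.n_subjects, _stage_int_seed(config.seed, "protocol"),
        exclude_learned=config.exclude_learned,
    )
    pdir = outdir / "protocol"
    pdir.mkdir(parents=True, exist_ok=True)
    for sub in subjects:
        for run in sub.runs:
            protocol.write_events(
                run.events, pdir / protocol.events_filename(sub.subject, run.run)
            )
    return subjects


def stage_simulate(config: PipelineConfig, outdir: Path, subjects) -> dict:
    """Simulated, run-normalized t-maps per (subject, ROI)."""
    tdir = outdir / "tmaps"
    tdir.mkdir(parents=True, exist_ok=True)
    out: dict[tuple[int, str], object] = {}
    for roi, amps in config.rois.items():
        for sub in subjects:
            # banks are per subject: ROIs live in native space, so there is
            # no voxel-pattern correspondence across individuals
            bank = simulate.sample_pattern_bank(
                config.n_voxels, stage_seed(config.seed, f"bank:{roi}:{sub.subject}"))
            rng = np.random.default_rng(
                stage_seed(config.seed, f"tmaps:{roi}:{sub.subject}"))
            tmaps = glm.normalize_tmaps(
                simulate.TmapSimulator(sub).simulate(bank, amps, rng))
            tmaps.to_csv(tdir / f"sub-{sub.subject:02d}_desc-{roi}_tmaps.csv")
            out[(sub.subject, roi)] = tmaps
    return out


def stage_rsa(config: PipelineConfig, outdir: Path, subjects, tmaps_by_key) -> dict:
    mdir = outdir / "matrices"
    mdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(stage_seed(config.seed, "rsa"))
    splits = _splits_for(config, rng)
    matrices: dict[tuple[int, str], dict] = {}
    for (subject, roi), tmaps in tmaps_by_key.items():
        pair = subjects[subject - 1].sequences
        mats = rsa.build_all_matrices(tmaps, pair, splits=splits)
        for kind, m in mats.items():
            m.to_csv(mdir / f"sub-{subject:02d}_desc-{roi}_{kind}.csv",
                     subject=subject, roi=roi)
        matrices[(subject, roi)] = mats
    return matrices


def stage_stats(config: PipelineConfig, outdir: Path, matrices) -> dict[str, pd.DataFrame]:
    sdir = outdir / "stats"
    sdir.mkdir(parents=True, exist_ok=True)
    rois = list(config.rois)
    n_rois = len(rois)

    delta_rows = []
    for (subject, roi), mats in matrices.items():
        for kind, m in mats.items():
            d = stats.delta_similarity(m, subject=subject, roi=roi)
            delta_rows.append({"subject": subject, "roi": roi, "kind": kind,
                               "diag_mean": d.diag_mean,
                               "offdiag_mean": d.offdiag_mean,
                               "delta": d.delta})
    deltas = pd.DataFrame(delta_rows).sort_values(
        ["roi", "kind", "subject"]).reset_index(drop=True)

    def _vec(roi, kind, col="delta"):
        sel = deltas[(deltas["roi"] == roi) & (deltas["kind"] == kind)]
        return sel.sort_values("subject")[col].to_numpy()

    test_rows = []
    for roi in rois:
        for kind in rsa.MATRIX_KINDS:
            res = stats.diag_vs_offdiag_test(
                _vec(roi, kind, "diag_mean"), _vec(roi, kind, "offdiag_mean"),
                n_comparisons=n_rois, method="bonferroni")
            p_corr = res.p_corrected
            if config.correction == "fdr_bh":
                p_corr = np.nan  # filled after the family is assembled
            test_rows.append({"roi": roi, "kind": kind, "t": res.statistic,
                              "df": res.df, "cohen_d": res.effect_size,
                              "p": res.p, "p_corrected": p_corr,
                              "method": config.correction, "note": res.note})
    coding = pd.DataFrame(test_rows)
    if config.correction == "fdr_bh":
        # FDR within each kind's family of ROIs
        for kind in rsa.MATRIX_KINDS:
            mask = coding["kind"] == kind
            coding.loc[mask, "p_corrected"] = stats.correct_pvalues(
                coding.loc[mask, "p"].to_numpy(), method="fdr_bh")

    reg_rows = []
    for roi in rois:
        for dv_kind, predictors in ATTRIBUTION_MODELS.items():
            X = pd.DataFrame({p: _vec(roi, p) for p in predictors})
            result = stats.stepwise_attribution(_vec(roi, dv_kind), X)
            for s in result.steps:
                reg_rows.append({
                    "roi": roi, "dv": dv_kind, "step": s.step,
                    "predictor": s.predictor, "B": s.coefficient,
                    "t": s.coefficient_t, "delta_r2": s.delta_r2, "F": s.f,
                    "df1": s.df1, "df2": s.df2, "p": s.p,
                    "p_corrected": min(1.0, s.p * n_rois),
                    "full_model_F": result.full_model_f,
                    "full_model_p": result.full_model_p,
                })
    regressions = pd.DataFrame(reg_rows)

    surr_rows = []
    rng = np.random.default_rng(stage_seed(config.seed, "surrogate"))
    corrected_deltas: dict[tuple[str, str], list[float]] = {}
    surrogate_deltas: dict[tuple[str, str], list] = {}
    for (subject, roi), mats in sorted(matrices.items()):
        for kind, m in mats.items():
            surr, corr = stats.surrogate_null(
                m, n_perm=config.n_perm,
                seed=rng.integers(0, 2**31 - 1))
            sd = stats.delta_similarity(surr)
            corrected_deltas.setdefault((roi, kind), []).append(
                stats.delta_similarity(corr).delta)
            surrogate_deltas.setdefault((roi, kind), []).append(
                (sd.diag_mean, sd.offdiag_mean))
    for (roi, kind), pairs in surrogate_deltas.items():
        diag = np.array([a for a, _ in pairs])
        off = np.array([b for _, b in pairs])
        surr_res = stats.diag_vs_offdiag_test(diag, off, n_comparisons=n_rois)
        corr_res = stats.one_sample_delta_test(
            np.asarray(corrected_deltas[(roi, kind)]), n_comparisons=n_rois)
        surr_rows.append({
            "roi": roi, "kind": kind,
            "surrogate_t": surr_res.statistic, "surrogate_p": surr_res.p,
            "surrogate_p_corrected": surr_res.p_corrected,
            "corrected_t": corr_res.statistic, "corrected_p": corr_res.p,
            "corrected_p_corrected": corr_res.p_corrected,
        })
    surrogate = pd.DataFrame(surr_rows)

    trim_rows = []
    for roi in rois:
        trimmed = [
            stats.delta_similarity(rsa.trim_boundaries(matrices[(s, roi)]["RD_POS"])).delta
            for s in sorted({k[0] for k in matrices})
        ]
        res = stats.one_sample_delta_test(np.asarray(trimmed), n_comparisons=n_rois)
        trim_rows.append({"roi": roi, "kind": "RD_POS_trimmed",
                          "t": res.statistic, "df": res.df,
                          "cohen_d": res.effect_size, "p": res.p,
                          "p_corrected": res.p_corrected})
    trimmed_tests = pd.DataFrame(trim_rows)

    tables = {"deltas": deltas, "coding_tests": coding,
              "regressions": regressions, "surrogate_tests": surrogate,
              "trimmed_tests": trimmed_tests}
    for name, df in tables.items():
        df.to_csv(sdir / f"{name}.csv", index=False)
    return tables


def run_pipeline(config: PipelineConfig, outdir: str | Path,
                 overwrite: bool = False) -> dict[str, pd.DataFrame]:
    """Run every stage and persist all artifacts; deterministic per config."""
    outdir = Path(outdir)
    if (outdir / "stats").exists() and not overwrite:
        raise FileExistsError(
            f"{outdir} already holds pipeline output; pass overwrite=True")
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")
    log: dict = {"seed": config.seed, "stages": {}}
    t0 = time.time()
    subjects = stage_protocol(config, outdir)
    log["stages"]["protocol"] = round(time.time() - t0, 3)
    t0 = time.time()
    tmaps_by_key = stage_simulate(config, outdir, subjects)
    log["stages"]["simulate"] = round(time.time() - t0, 3)
    t0 = time.time()
    matrices = stage_rsa(config, outdir, subjects, tmaps_by_key)
    log["stages"]["rsa"] = round(time.time() - t0, 3)
    t0 = time.time()
    tables = stage_stats(config, outdir, matrices)
    log["stages"]["stats"] = round(time.time() - t0, 3)
    log["versions"] = {"numpy": np.__version__, "pandas": pd.__version__}
    (outdir / "log.json").write_text(json.dumps(log, indent=2))
    return tables


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------

def _protocol_checks(pdir: Path) -> dict:
    """Re-verify the protocol bookkeeping from the persisted TSVs."""
    files = sorted(pdir.glob("sub-*_run-*_events.tsv"))
    per_run_events_ok = True
    per_cond_ok = True
    max2_ok = True
    reps: dict[int, dict[str, int]] = {}
    for f in files:
        ev = protocol.read_events(f)
        if len(ev) != 120:
            per_run_events_ok = False
        counts = ev.groupby("condition")["block"].nunique()
        if not (counts == 5).all():
            per_cond_ok = False
        order = ev.drop_duplicates("block")["condition"].tolist()
        if any(len(set(order[i:i + 3])) == 1 for i in range(len(order) - 2)):
            max2_ok = False
        sub = int(ev["subject"].iloc[0])
        for c, k in counts.items():
            reps.setdefault(sub, {}).setdefault(c, 0)
            reps[sub][c] += int(k)
    reps_ok = all(all(v == 40 for v in d.values()) for d in reps.values())
    return {"n_event_files": len(files),
            "events_per_run_is_120": per_run_events_ok,
            "five_blocks_per_condition_per_run": per_cond_ok,
            "max_two_consecutive": max2_ok,
            "forty_repetitions_per_condition": reps_ok}


def make_report(artifact_dir: str | Path) -> dict:
    """Summarize a finished run into ``report.json`` (idempotent).

    One machine-readable section per analysis family, plus a re-check of
    the protocol counts from the persisted event files.
    """
    artifact_dir = Path(artifact_dir)
    required = ["protocol", "stats"]
    missing = [d for d in required if not (artifact_dir / d).exists()]
    if missing:
        raise FileNotFoundError(
            f"incomplete artifact directory; missing stage(s): {missing}")
    coding = pd.read_csv(artifact_dir / "stats" / "coding_tests.csv")
    regressions = pd.read_csv(artifact_dir / "stats" / "regressions.csv")
    surrogate = pd.read_csv(artifact_dir / "stats" / "surrogate_tests.csv")
    trimmed = pd.read_csv(artifact_dir / "stats" / "trimmed_tests.csv")
    report = {
        "coding": {
            f"{row.roi}/{row.kind}": {
                "t": None if pd.isna(row.t) else round(float(row.t), 3),
                "p_corrected": round(float(row.p_corrected), 5),
                "significant": bool(row.p_corrected < 0.05),
            }
            for row in coding.itertuples()
        },
        "regressions": {
            f"{row.roi}/{row.dv}/step{row.step}": {
                "predictor": row.predictor,
                "delta_r2": round(float(row.delta_r2), 4),
                "p": round(float(row.p), 5),
            }
            for row in regressions.itertuples()
        },
        "surrogate": {
            f"{row.roi}/{row.kind}": {
                "surrogate_diag_vs_offdiag_p": round(float(row.surrogate_p), 5),
                "corrected_delta_p": round(float(row.corrected_p), 5),
            }
            for row in surrogate.itertuples()
        },
        "boundary_trimmed": {
            row.roi: {"p_corrected": round(float(row.p_corrected), 5),
                      "significant": bool(row.p_corrected < 0.05)}
            for row in trimmed.itertuples()
        },
        "protocol_checks": _protocol_checks(artifact_dir / "protocol"),
    }
    (artifact_dir / "report.json").write_text(json.dumps(report, indent=2))
    return report
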