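"""Study-level orchestration: per-subject analysis and study aggregation.

A study is a directory (or in-memory dict) of subjects, each holding one
quiet "story" trial used to train the backward decoder and a set of Matrix
test trials spanning conditions and SNRs.  For each subject the pipeline
runs: preprocessing -> decoder training on the story -> envelope
reconstruction and bootstrapped Spearman tracking on every test trial ->
forward TRF estimation on the quiet trials.  The study step then assembles
the tracking table, SNR-tracking correlations per condition and their
comparison, per-SNR paired permutation tests, neural psychometric (SRT)
fits, variance-homogeneity checks, and the channel x lag cluster
permutation analysis of TRF differences.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import preprocess as pre
from . import stats as st
from .channels import build_adjacency
from .containers import EEGRecording, EnvelopeSignal
from .linear_model import (LagSpec, bootstrap_spearman, reconstruct,
                           train_backward, train_forward)
from .synthetic import Trial, load_study

logger = logging.getLogger("envtrack")

__all__ = ["AnalysisConfig", "run_subject", "run_study", "StudyReport"]


@dataclass
class AnalysisConfig:
    """Configuration of one full analysis run (losslessly serializable)."""

    band: str = "delta"                 # "delta" (0.5-4 Hz) or "theta" (4-8 Hz)
    lags_ms: tuple = (0.0, 500.0)       # decoder integration window
    trf_lags_ms: tuple = (0.0, 500.0)
    fs_intermediate: float = 256.0
    fs_final: float = 128.0
    blank_uv: float = 500.0
    mwf: bool = True
    mwf_power_factor: float = 5.0
    mwf_delay_span: int = 3
    n_boot: int = 1000
    block_s: float = 5.0
    train_condition: str = "story"
    k_bins: int = 7
    n_perm: int = 5000
    cluster_alpha: float = 0.05
    n_boot_psychometric: int = 200
    seed: int = 0

    def to_json(self, path=None) -> str:
        obj = asdict(self)
        obj["lags_ms"] = list(self.lags_ms)
        obj["trf_lags_ms"] = list(self.trf_lags_ms)
        text = json.dumps(obj, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, text_or_path) -> "AnalysisConfig":
        try:
            obj = json.loads(text_or_path)
        except (json.JSONDecodeError, TypeError):
            obj = json.loads(Path(text_or_path).read_text())
        obj["lags_ms"] = tuple(obj["lags_ms"])
        obj["trf_lags_ms"] = tuple(obj["trf_lags_ms"])
        return cls(**obj)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


def _preprocess_eeg(eeg: EEGRecording, config: AnalysisConfig,
                    band=None) -> EEGRecording:
    out = pre.blank_and_interpolate(eeg, threshold=config.blank_uv)
    if out.fs != config.fs_intermediate:
        out = pre.resample(out, config.fs_intermediate)
    if config.mwf:
        out, _ = pre.mwf_denoise(out,
                                 power_factor=config.mwf_power_factor,
                                 delay_span=config.mwf_delay_span)
    out = pre.rereference_average(out)
    if band is not None:
        out = pre.bandpass(out, band)
    return pre.resample(out, config.fs_final)


def _preprocess_env(env: EnvelopeSignal, config: AnalysisConfig,
                    band=None) -> EnvelopeSignal:
    out = env
    if out.fs != config.fs_intermediate:
        out = pre.resample(out, config.fs_intermediate)
    if band is not None:
        out = pre.bandpass(out, band)
    return pre.resample(out, config.fs_final)


def _match_lengths(a, b):
    n = min(a.n_samples, b.n_samples)
    if isinstance(a, EEGRecording):
        a = a.copy(data=a.data[:, :n])
    else:
        a = a.copy(samples=a.samples[:n])
    b = b.copy(samples=b.samples[:n]) if isinstance(b, EnvelopeSignal) \
        else b.copy(data=b.data[:, :n])
    return a, b


def run_subject(trials, config: AnalysisConfig = None):
    """Analyze one subject.

    ``trials`` is a list of :class:`~envtrack.synthetic.Trial` or a subject
    directory in the interchange layout.  Returns ``(rows, trfs)`` where
    ``rows`` is a list of tracking-table dicts (one per condition x SNR
    after averaging repeated presentations) and ``trfs`` maps each
    condition to the forward TRF estimated from its quiet trials.
    """
    if config is None:
        config = AnalysisConfig()
    if isinstance(trials, (str, Path)):
        sdir = Path(trials)
        study = load_study(sdir.parent)
        trials = study[sdir.name]
    is_train = [t.role == "train" or t.condition == config.train_condition
                for t in trials]
    train = [t for t, flag in zip(trials, is_train) if flag]
    if not train:
        raise ValueError("no training (story) trial in dataset")
    tests = [t for t, flag in zip(trials, is_train) if not flag]

    band = config.band
    lagspec = LagSpec(*config.lags_ms, fs=config.fs_final)
    trf_lagspec = LagSpec(*config.trf_lags_ms, fs=config.fs_final)

    eeg_tr = _preprocess_eeg(train[0].eeg, config, band)
    env_tr = _preprocess_env(train[0].envelope, config, band)
    eeg_tr, env_tr = _match_lengths(eeg_tr, env_tr)
    decoder = train_backward(eeg_tr, env_tr, lagspec, band=pre.BANDS[band])

    raw = []
    quiet = {}  # condition -> list of (eeg, env) without band filtering
    for i, tr in enumerate(tests):
        try:
            eeg = _preprocess_eeg(tr.eeg, config, band)
            env = _preprocess_env(tr.envelope, config, band)
            eeg, env = _match_lengths(eeg, env)
            s_hat = reconstruct(decoder, eeg)
            score = bootstrap_spearman(env, s_hat, n_boot=config.n_boot,
                                       seed=config.seed + i,
                                       block_s=config.block_s)
            raw.append({"subject": tr.subject, "condition": tr.condition,
                        "snr": tr.snr, "rho": score.rho_median,
                        "ci_low": score.ci_low, "ci_high": score.ci_high,
                        "n_boot": score.n_boot})
            if tr.snr is None:
                # TRFs are estimated on broadband (unfiltered) data.
                eeg_bb = _preprocess_eeg(tr.eeg, config, band=None)
                env_bb = _preprocess_env(tr.envelope, config, band=None)
                eeg_bb, env_bb = _match_lengths(eeg_bb, env_bb)
                quiet.setdefault(tr.condition, []).append((env_bb, eeg_bb))
        except Exception:
            logger.exception("trial %s/%s/%s failed; skipping",
                             tr.subject, tr.condition, tr.snr)

    # average repeated presentations per condition x SNR
    rows = []
    df = pd.DataFrame(raw)
    if not df.empty:
        group = df.groupby(["subject", "condition", "snr"], dropna=False)
        for (subj, cond, snr), g in group:
            rows.append({"subject": subj, "condition": cond,
                         "snr": None if pd.isna(snr) else float(snr),
                         "rho": float(g["rho"].mean()),
                         "ci_low": float(g["ci_low"].mean()),
                         "ci_high": float(g["ci_high"].mean()),
                         "n_boot": int(g["n_boot"].iloc[0]),
                         "band": band,
                         "lags": f"{config.lags_ms[0]:g}-{config.lags_ms[1]:g}ms"})

    trfs = {}
    for cond, pairs in quiet.items():
        env_cat = EnvelopeSignal(
            np.concatenate([e.samples for e, _ in pairs]), fs=config.fs_final)
        eeg_cat = EEGRecording(
            np.concatenate([r.data for _, r in pairs], axis=1),
            fs=config.fs_final, labels=pairs[0][1].labels)
        trfs[cond] = train_forward(env_cat, eeg_cat, trf_lagspec)
    return rows, trfs


@dataclass
class StudyReport:
    """Aggregated study-level results."""

    tracking: pd.DataFrame
    snr_correlations: dict          # condition -> (rho, p)
    correlation_comparison: float | None
    per_bin_p: dict                 # bin center -> Holm-adjusted p
    brown_forsythe: dict            # bin center -> (stat, p)
    psychometric: dict              # condition -> PsychometricFit + CI
    cluster: object | None
    config_hash: str
    notices: list = field(default_factory=list)

    def save(self, outdir):
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.tracking.to_csv(outdir / "tracking.csv", index=False)
        summary = {
            "config_hash": self.config_hash,
            "snr_correlations": {c: list(v) for c, v in
                                 self.snr_correlations.items()},
            "correlation_comparison_p": self.correlation_comparison,
            "per_bin_p": {str(k): v for k, v in self.per_bin_p.items()},
            "brown_forsythe": {str(k): list(v) for k, v in
                               self.brown_forsythe.items()},
            "psychometric": {c: {"alpha": f.alpha, "beta": f.beta,
                                 "guess": f.guess, "lapse": f.lapse,
                                 "slope_pct_per_db": f.slope_pct_per_db,
                                 "fit_ok": f.fit_ok, "ci": f.ci}
                             for c, f in self.psychometric.items()},
            "notices": self.notices,
        }
        if self.cluster is not None:
            summary["clusters"] = [
                {"channels": c.channels, "lag_range_ms": list(c.lag_range_ms),
                 "mass": c.mass, "p": c.p_value}
                for c in self.cluster.clusters]
            rows = [{"p": c.p_value, "mass": c.mass,
                     "lag_lo_ms": c.lag_range_ms[0],
                     "lag_hi_ms": c.lag_range_ms[1],
                     "n_channels": len(c.channels),
                     "channels": " ".join(map(str, c.channels))}
                    for c in self.cluster.clusters]
            pd.DataFrame(rows).to_csv(outdir / "clusters.csv", index=False)
        with open(outdir / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=1)


def run_study(study, config: AnalysisConfig = None,
              outdir=None) -> StudyReport:
    """Run the full analysis over a study directory or in-memory dict."""
    if config is None:
        config = AnalysisConfig()
    if isinstance(study, (str, Path)):
        study = load_study(study)
    if len(study) < 2:
        raise ValueError("need at least two subjects")

    notices = []
    all_rows, subj_trfs = [], {}
    for subject, trials in study.items():
        rows, trfs = run_subject(trials, config)
        all_rows.extend(rows)
        subj_trfs[subject] = trfs
    tracking = pd.DataFrame(all_rows)

    # --- SNR binning (quiet trials form their own bin) -------------------
    finite = tracking[tracking["snr"].notna()].copy()
    distinct = finite["snr"].nunique()
    k = min(config.k_bins, distinct) if distinct else 0
    if k:
        labels, centers = st.bin_snrs(finite["snr"].to_numpy(), k=k,
                                      seed=config.seed)
        finite["bin_center"] = centers[labels]
        tracking = tracking.merge(
            finite[["subject", "condition", "snr", "bin_center"]],
            on=["subject", "condition", "snr"], how="left")
    else:
        tracking["bin_center"] = np.nan
    tracking.loc[tracking["snr"].isna(), "bin_center"] = np.inf  # quiet

    conditions = sorted(c for c in tracking["condition"].unique())
    # mean per subject x condition x bin (the tracking table proper)
    table = (tracking.groupby(["subject", "condition", "bin_center"])
             .agg(rho=("rho", "mean"), ci_low=("ci_low", "mean"),
                  ci_high=("ci_high", "mean"))
             .reset_index())

    # --- SNR vs tracking correlations per condition ----------------------
    snr_corr = {}
    for cond in conditions:
        sub = table[(table["condition"] == cond)
                    & np.isfinite(table["bin_center"])]
        if sub["bin_center"].nunique() > 1:
            res = st.sstats.spearmanr(sub["bin_center"], sub["rho"])
            snr_corr[cond] = (float(res.statistic), float(res.pvalue))

    comparison = None
    per_bin_p, bf = {}, {}
    psychometric = {}
    cluster = None

    pair = [c for c in ("attention", "movie") if c in conditions]
    if len(pair) == 2:
        wide = table.pivot_table(index=["subject", "bin_center"],
                                 columns="condition", values="rho").dropna()
        finite_wide = wide[np.isfinite(
            wide.index.get_level_values("bin_center"))]
        if len(finite_wide) >= 4:
            snr_vals = finite_wide.index.get_level_values("bin_center")
            ra = st.sstats.spearmanr(snr_vals, finite_wide[pair[0]]).statistic
            rb = st.sstats.spearmanr(snr_vals, finite_wide[pair[1]]).statistic
            rab = st.sstats.spearmanr(finite_wide[pair[0]],
                                      finite_wide[pair[1]]).statistic
            if all(abs(r) < 1 for r in (ra, rb, rab)):
                comparison = st.compare_dependent_correlations(
                    ra, rb, rab, n=len(finite_wide))
            else:
                notices.append("degenerate (|r|=1) correlations: "
                               "comparison skipped")
        x = {}
        y = {}
        for center, g in wide.groupby(level="bin_center"):
            x[center] = g[pair[0]].to_numpy()
            y[center] = g[pair[1]].to_numpy()
        if x:
            per_bin_p = st.paired_permutation_by_snr(
                x, y, n_perm=config.n_perm, seed=config.seed)
            for center in x:
                if len(x[center]) >= 2:
                    bf[center] = st.brown_forsythe(x[center], y[center])
        trf_a = [subj_trfs[s][pair[0]] for s in subj_trfs
                 if pair[0] in subj_trfs[s] and pair[1] in subj_trfs[s]]
        trf_b = [subj_trfs[s][pair[1]] for s in subj_trfs
                 if pair[0] in subj_trfs[s] and pair[1] in subj_trfs[s]]
        if len(trf_a) >= 5:
            adjacency = build_adjacency(trf_a[0].labels)
            cluster = st.cluster_permutation(
                trf_a, trf_b, adjacency=adjacency,
                cluster_alpha=config.cluster_alpha,
                n_perm=config.n_perm, seed=config.seed)
        else:
            notices.append("fewer than 5 paired TRFs: cluster test skipped")
    else:
        notices.append("single condition: comparison analyses skipped")

    # --- neural psychometric fit per condition ---------------------------
    rng = np.random.default_rng(config.seed)
    for cond in conditions:
        sub = table[(table["condition"] == cond)
                    & np.isfinite(table["bin_center"])]
        if sub["bin_center"].nunique() < 4:
            continue
        fit = st.fit_psychometric(sub["bin_center"].to_numpy(),
                                  np.clip(sub["rho"].to_numpy(), 0, 1),
                                  fix_rates=False)
        subjects = sub["subject"].unique()
        alphas = []
        for _ in range(config.n_boot_psychometric):
            pick = rng.choice(subjects, size=len(subjects), replace=True)
            boot = pd.concat([sub[sub["subject"] == s] for s in pick])
            try:
                bf_fit = st.fit_psychometric(
                    boot["bin_center"].to_numpy(),
                    np.clip(boot["rho"].to_numpy(), 0, 1), fix_rates=False)
                if bf_fit.fit_ok:
                    alphas.append(bf_fit.alpha)
            except ValueError:
                continue
        if alphas:
            fit.ci = (float(np.percentile(alphas, 2.5)),
                      float(np.percentile(alphas, 97.5)))
        psychometric[cond] = fit

    report = StudyReport(tracking=table, snr_correlations=snr_corr,
                         correlation_comparison=comparison,
                         per_bin_p=per_bin_p, brown_forsythe=bf,
                         psychometric=psychometric, cluster=cluster,
                         config_hash=config.config_hash, notices=notices)
    if outdir is not None:
        report.save(outdir)
        config.to_json(Path(outdir) / "config.json")
    return report
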