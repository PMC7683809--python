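"""End-to-end orchestration: simulate → preprocess → measures → inference.

A single configured, seeded, deterministic run that emits the full tidy
result-table suite for a cohort:

* per-subject PSD curves per region and coherence curves per circuit
  (velocity-gated 5–15 cm/s epochs concatenated per subject, and per estrous
  stage for females), with band means;
* per-trial theta power correlations and theta phase-lag widths per circuit,
  plus pooled (all trials combined) phase-lag distributions;
* hierarchical-bootstrap sex and estrous comparisons with the matching alpha
  policy, functional curve tests, and the within-subject circuit omnibus.

Trials are processed subject by subject so memory stays bounded by one
subject's recordings.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as tio
from .preprocess import concatenate_epochs, preprocess_trial, velocity_epochs
from .spectral import BANDS, band_mean, coherence, welch_psd
from .stats import (
    ESTROUS_COMPARISON_STAGES,
    GroupedValues,
    alpha_policy,
    circuit_comparison,
    compare_grouped,
    functional_anova,
    functional_two_sample_F,
)
from .synthetic import CIRCUITS, REGIONS, CohortConfig, simulate_trial
from .theta_coupling import (
    dhpc_power_gate,
    phase_lag_distribution,
    pooled_distribution,
    power_correlation,
    theta_filter,
    theta_power_series,
    width_at_half_max,
)

__all__ = ["RunConfig", "ResultBundle", "StageError", "run", "report"]

log = logging.getLogger("thetalink")


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass(frozen=True)
class RunConfig:
    """All analysis-relevant parameters of a run.

    Defaults equal the study's printed parameters: PLV threshold 0.6,
    velocity gate 5–15 cm/s, Welch 0.4 s / 90% / 4000-point FFT, coherence
    2 s Hann / 50%, theta power 2.5 s / NW 2.5 / 2048-point FFT, pi/100
    phase bins, 10^4 bootstrap replicates.
    """

    cohort: CohortConfig = None
    input_dir: str | None = None
    out_dir: str | None = None
    plv_threshold: float = 0.6
    vmin: float = 5.0
    vmax: float = 15.0
    min_epoch_s: float = 0.5
    psd_window_s: float = 0.4
    psd_overlap: float = 0.9
    psd_nfft: int = 4000
    coh_window_s: float = 2.0
    coh_overlap: float = 0.5
    power_window_s: float = 2.5
    power_nw: float = 2.5
    power_nfft: int = 2048
    n_boot: int = 10_000
    n_perm: int = 500
    seed: int = 0
    comparisons: tuple[str, ...] = ("circuits", "sex", "estrous")

    def config_hash(self) -> str:
        d = asdict(self)
        d.pop("out_dir")
        blob = json.dumps(d, sort_keys=True, default=repr).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class ResultBundle:
    """All emitted tables plus run metadata."""

    config_hash: str
    seed: int
    spectra: pd.DataFrame
    band_means: pd.DataFrame
    power_correlations: pd.DataFrame
    phase_widths: pd.DataFrame
    pooled_widths: pd.DataFrame
    comparisons: pd.DataFrame
    functional_tests: pd.DataFrame
    circuit_omnibus: pd.DataFrame
    stage_log: list[str] = field(default_factory=list)
    out_dir: str | None = None


def _circuit_name(pair: tuple[str, str]) -> str:
    return f"{pair[0]}-{pair[1]}"


def _iter_trials(config: RunConfig):
    """Yield (subject_id, sex, [TrialRecording...]) one subject at a time."""
    if config.input_dir is not None:
        manifest = tio.read_manifest(config.input_dir)
        root = Path(config.input_dir)
        for sid, g in manifest.groupby("subject_id", sort=False):
            trials = [tio.load_trial(root / p) for p in g["path"]]
            yield sid, trials[0].sex, trials
    elif config.cohort is not None:
        cc = config.cohort
        counts = cc.trial_counts()
        for (sid, sex), n_tr in zip(cc.subjects, counts):
            yield sid, sex, [simulate_trial(cc, sid, k) for k in range(n_tr)]
    else:
        raise StageError("input: neither a cohort config nor an input dir given")


def _subject_measures(trials, config: RunConfig):
    """Per-trial coupling measures + per-subject concatenated gated series."""
    rows_pc, rows_pw = [], []
    dists_by_circuit: dict[str, list] = {_circuit_name(c): [] for c in CIRCUITS}
    rsets, epochs = [], []
    for trial in trials:
        rset = preprocess_trial(trial, plv_threshold=config.plv_threshold)
        eps = velocity_epochs(rset.velocity, lo=config.vmin, hi=config.vmax,
                              min_dur_s=config.min_epoch_s, fs=rset.fs)
        meta = dict(trial_id=rset.trial_id, subject_id=rset.subject_id,
                    sex=rset.sex, estrous=rset.estrous)
        # theta power correlations (full trial, all velocities)
        tps = theta_power_series(rset, window_s=config.power_window_s,
                                 nw=config.power_nw, nfft=config.power_nfft)
        theta = {r: theta_filter(rset.traces[r], rset.fs) for r in rset.traces}
        gate = dhpc_power_gate(rset.traces["dHPC"], rset.fs)
        for circ in CIRCUITS:
            name = _circuit_name(circ)
            pc = power_correlation(tps.power[circ[0]], tps.power[circ[1]],
                                   region_pair=circ, trial_id=rset.trial_id)
            rows_pc.append({**meta, "pair": name, "r": pc.r, "r2": pc.r2,
                            "p": pc.p})
            dist = phase_lag_distribution(theta[circ[0]], theta[circ[1]],
                                          rset.fs, gate_mask=gate,
                                          region_pair=circ,
                                          trial_id=rset.trial_id,
                                          prefiltered=True)
            dists_by_circuit[name].append(dist)
            rows_pw.append({**meta, "pair": name,
                            "width_hm": width_at_half_max(dist),
                            "n_gated": dist.n_samples})
        # keep only what spectral estimation needs
        rset.traces = {r: t.astype(np.float32) for r, t in rset.traces.items()}
        rsets.append(rset)
        epochs.append(eps)
    return rows_pc, rows_pw, dists_by_circuit, rsets, epochs


def _subject_spectra(rsets, epochs, config: RunConfig):
    """Per-subject (and per-stage) PSD and coherence on gated concatenations."""
    rows_spec, rows_band = [], []
    subject_id, sex = rsets[0].subject_id, rsets[0].sex
    stage_sets = {"all": list(range(len(rsets)))}
    if sex == "F":
        for stage in ESTROUS_COMPARISON_STAGES:
            idx = [i for i, rs in enumerate(rsets) if rs.estrous == stage]
            if idx:
                stage_sets[stage] = idx
    for stage, idx in stage_sets.items():
        sel_r = [rsets[i] for i in idx]
        sel_e = [epochs[i] for i in idx]
        if sum(e.total_samples() for e in sel_e) == 0:
            continue
        series = concatenate_epochs(sel_r, sel_e)
        # a stage with no epoch long enough for the coherence window yields no
        # curve for that stage rather than aborting the subject
        longest = max(e - s for s, e in series.segments())
        if longest < config.coh_window_s * series.fs:
            log.warning("subject %s stage %s: longest gated epoch %.2f s < "
                        "coherence window; stage skipped", subject_id, stage,
                        longest / series.fs)
            continue
        meta = dict(subject_id=subject_id, sex=sex, estrous=stage)
        for region in REGIONS:
            trace = series.traces[region].astype(np.float64)
            psd = welch_psd(trace, series.fs, window_s=config.psd_window_s,
                            overlap=config.psd_overlap, nfft=config.psd_nfft,
                            boundaries=series.boundaries)
            rows_spec.extend({**meta, "kind": "psd", "region_or_pair": region,
                              "freq": f, "value": v}
                             for f, v in zip(psd.freqs, psd.values))
            for b in BANDS.values():
                rows_band.append({**meta, "kind": "psd",
                                  "region_or_pair": region, "band": b.name,
                                  "value": band_mean(psd, b)})
        for circ in CIRCUITS:
            name = _circuit_name(circ)
            coh = coherence(series.traces[circ[0]].astype(np.float64),
                            series.traces[circ[1]].astype(np.float64),
                            series.fs, window_s=config.coh_window_s,
                            overlap=config.coh_overlap,
                            boundaries=series.boundaries)
            rows_spec.extend({**meta, "kind": "coherence",
                              "region_or_pair": name, "freq": f, "value": v}
                             for f, v in zip(coh.freqs, coh.values))
            for b in BANDS.values():
                rows_band.append({**meta, "kind": "coherence",
                                  "region_or_pair": name, "band": b.name,
                                  "value": band_mean(coh, b)})
    return rows_spec, rows_band


def _grouped(df: pd.DataFrame, mask, label: str, value_col: str) -> GroupedValues:
    return GroupedValues.from_frame(df[mask], label, value_col)


def _bootstrap_comparisons(pc: pd.DataFrame, pw: pd.DataFrame, config: RunConfig):
    """Sex and estrous hierarchical-bootstrap comparisons per circuit."""
    rows = []
    specs = []  # (measure, frame, value_col)
    specs.append(("power_correlation_r2", pc, "r2"))
    specs.append(("phase_width", pw, "width_hm"))
    child = np.random.SeedSequence(config.seed).spawn(1)[0]
    seeds = iter(int(s.generate_state(1)[0] % (2**31)) for s in child.spawn(4096))
    for measure, df, col in specs:
        for circ in CIRCUITS:
            name = _circuit_name(circ)
            sub = df[df["pair"] == name]
            if "sex" in config.comparisons and set(sub["sex"]) == {"F", "M"}:
                ga = _grouped(sub, sub["sex"] == "F", "F", col)
                gb = _grouped(sub, sub["sex"] == "M", "M", col)
                cmp_ = compare_grouped(ga, gb, n_boot=config.n_boot,
                                       seed=next(seeds))
                alpha = alpha_policy("two-group")
                rows.append({"measure": measure, "pair": name, "group_a": "F",
                             "group_b": "M", "n_boot": config.n_boot,
                             "seed": cmp_.seed, "p_boot": cmp_.p_boot,
                             "p_two": cmp_.p_two, "alpha": alpha,
                             "significant": cmp_.p_two < alpha})
            if "estrous" in config.comparisons:
                fem = sub[(sub["sex"] == "F")
                          & sub["estrous"].isin(ESTROUS_COMPARISON_STAGES)]
                stages = [s for s in ESTROUS_COMPARISON_STAGES
                          if (fem["estrous"] == s).any()]
                for i in range(len(stages)):
                    for j in range(i + 1, len(stages)):
                        sa, sb = stages[i], stages[j]
                        ga = _grouped(fem, fem["estrous"] == sa, sa, col)
                        gb = _grouped(fem, fem["estrous"] == sb, sb, col)
                        cmp_ = compare_grouped(ga, gb, n_boot=config.n_boot,
                                               seed=next(seeds))
                        alpha = alpha_policy("estrous-pairwise")
                        rows.append({"measure": measure, "pair": name,
                                     "group_a": sa, "group_b": sb,
                                     "n_boot": config.n_boot, "seed": cmp_.seed,
                                     "p_boot": cmp_.p_boot, "p_two": cmp_.p_two,
                                     "alpha": alpha,
                                     "significant": cmp_.p_two < alpha})
    return rows


def _functional_tests(spectra: pd.DataFrame, config: RunConfig):
    """Curve-shape tests: sex (two-sample) and estrous (ANOVA) per curve."""
    rows = []
    child = np.random.SeedSequence([config.seed, 7]).spawn(4096)
    seeds = iter(int(s.generate_state(1)[0] % (2**31)) for s in child)
    for kind in ("psd", "coherence"):
        sub_all = spectra[(spectra["kind"] == kind)
                          & (spectra["estrous"] == "all")]
        for target, g in sub_all.groupby("region_or_pair", sort=False):
            piv = g.pivot_table(index="subject_id", columns="freq",
                                values="value", sort=False)
            sexes = g.drop_duplicates("subject_id").set_index("subject_id")["sex"]
            if "sex" in config.comparisons and set(sexes) == {"F", "M"}:
                a = piv.loc[sexes[sexes == "F"].index].to_numpy()
                b = piv.loc[sexes[sexes == "M"].index].to_numpy()
                if min(a.shape[0], b.shape[0]) < 2:
                    log.warning("functional sex test for %s skipped: a group "
                                "has < 2 subjects", target)
                    continue
                res = functional_two_sample_F(a, b, n_perm=config.n_perm,
                                              seed=next(seeds))
                rows.append({"kind": kind, "region_or_pair": target,
                             "comparison": "sex", "statistic": res.statistic,
                             "p": res.p, "n_perm": res.n_perm})
        if "estrous" not in config.comparisons:
            continue
        fem = spectra[(spectra["kind"] == kind) & (spectra["sex"] == "F")
                      & spectra["estrous"].isin(ESTROUS_COMPARISON_STAGES)]
        for target, g in fem.groupby("region_or_pair", sort=False):
            curves = {}
            for stage, gs in g.groupby("estrous", sort=False):
                piv = gs.pivot_table(index="subject_id", columns="freq",
                                     values="value", sort=False)
                if len(piv) >= 2:
                    curves[stage] = piv.to_numpy()
            if len(curves) >= 2:
                res = functional_anova(curves, n_perm=config.n_perm,
                                       seed=next(seeds))
                rows.append({"kind": kind, "region_or_pair": target,
                             "comparison": "estrous", "statistic": res.statistic,
                             "p": res.p, "n_perm": res.n_perm})
    return rows


def run(config: RunConfig) -> ResultBundle:
    """Execute the full pipeline; deterministic for a fixed config."""
    stage_log = []
    rows_pc, rows_pw, rows_spec, rows_band, rows_pooled = [], [], [], [], []
    pooled_acc: dict[str, list] = {_circuit_name(c): [] for c in CIRCUITS}

    stage = "measures"
    try:
        for sid, sex, trials in _iter_trials(config):
            log.info("subject %s (%s): %d trials", sid, sex, len(trials))
            pc, pw, dists, rsets, epochs = _subject_measures(trials, config)
            rows_pc.extend(pc)
            rows_pw.extend(pw)
            for name, ds in dists.items():
                pooled_acc[name].extend(ds)
            stage = "spectral"
            rs, rb = _subject_spectra(rsets, epochs, config)
            rows_spec.extend(rs)
            rows_band.extend(rb)
            stage = "measures"
        stage = "pooled"
        for circ in CIRCUITS:
            name = _circuit_name(circ)
            pooled = pooled_distribution(pooled_acc[name], region_pair=circ)
            rows_pooled.append({"pair": name,
                                "width_hm": width_at_half_max(pooled),
                                "n_samples": pooled.n_samples})
        pc_df = pd.DataFrame(rows_pc)
        pw_df = pd.DataFrame(rows_pw)
        spectra = pd.DataFrame(rows_spec)
        bands = pd.DataFrame(rows_band)
        pooled_df = pd.DataFrame(rows_pooled)

        stage = "stats"
        cmp_rows = _bootstrap_comparisons(pc_df, pw_df, config)
        fun_rows = _functional_tests(spectra, config)
        omni_rows = []
        if "circuits" in config.comparisons:
            for measure, df, col in (("power_correlation_r2", pc_df, "r2"),
                                     ("phase_width", pw_df, "width_hm")):
                means = df.pivot_table(index="subject_id", columns="pair",
                                       values=col, aggfunc="mean", sort=False)
                if len(means) >= 3:
                    cc = circuit_comparison(means)
                    omni_rows.append({"measure": measure, "method": cc.method,
                                      "statistic": cc.statistic, "p": cc.p,
                                      "normality_p": cc.normality_p})
                    for _, r in cc.posthoc.iterrows():
                        omni_rows.append({"measure": measure,
                                          "method": cc.method + "_posthoc",
                                          "pair_a": r["pair_a"],
                                          "pair_b": r["pair_b"],
                                          "statistic": r["statistic"],
                                          "p": r["p"]})
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001 - stage-named rewrap
        raise StageError(f"{stage}: {exc}") from exc

    bundle = ResultBundle(
        config_hash=config.config_hash(), seed=config.seed,
        spectra=spectra, band_means=bands, power_correlations=pc_df,
        phase_widths=pw_df, pooled_widths=pooled_df,
        comparisons=pd.DataFrame(cmp_rows),
        functional_tests=pd.DataFrame(fun_rows),
        circuit_omnibus=pd.DataFrame(omni_rows),
        stage_log=stage_log, out_dir=config.out_dir,
    )
    if config.out_dir is not None:
        _write_bundle(bundle, config)
    return bundle


def _write_bundle(bundle: ResultBundle, config: RunConfig):
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tables = {
        "spectra.csv": bundle.spectra,
        "band_means.csv": bundle.band_means,
        "power_correlations.csv": bundle.power_correlations,
        "phase_widths.csv": bundle.phase_widths,
        "pooled_widths.csv": bundle.pooled_widths,
        "comparisons.csv": bundle.comparisons,
        "functional_tests.csv": bundle.functional_tests,
        "circuit_omnibus.csv": bundle.circuit_omnibus,
    }
    for name, df in tables.items():
        df.to_csv(out / name, index=False, float_format="%.10g")
    meta = {"config_hash": bundle.config_hash, "seed": bundle.seed,
            "tables": sorted(tables)}
    (out / "run_manifest.json").write_text(json.dumps(meta, indent=2))


def report(bundle: ResultBundle) -> dict[str, pd.DataFrame]:
    """Human-readable summary: per-group subject means ± SEM + significance."""
    for attr in ("power_correlations", "phase_widths", "comparisons"):
        if getattr(bundle, attr) is None:
            raise ValueError(f"incomplete bundle: missing {attr}")
    out = {}
    for measure, df, col in (("power_correlation_r2", bundle.power_correlations, "r2"),
                             ("phase_width", bundle.phase_widths, "width_hm")):
        if df.empty:
            out[measure] = pd.DataFrame()
            continue
        subj = (df.groupby(["pair", "sex", "subject_id"])[col].mean()
                  .reset_index())
        summ = subj.groupby(["pair", "sex"])[col].agg(
            mean="mean", sem=lambda v: v.std(ddof=1) / np.sqrt(len(v)) if len(v) > 1 else np.nan,
            n_subjects="count").reset_index()
        out[measure] = summ
    cmp_df = bundle.comparisons
    out["comparisons"] = cmp_df if cmp_df is not None else pd.DataFrame()
    return out
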