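"""Significance testing, multiple-comparison corrections, and the pipeline.

Differences between conditions are tested nonparametrically: a Wilcoxon
signed-rank test against zero for paired per-unit differences (e.g. the
bootstrap-averaged d' of each electrode), and a Wilcoxon rank-sum test for
comparisons between two independent sets of units.  When comparing d'
magnitudes, negative values are sign-flipped before testing.  Families of
tests are corrected with Bonferroni, Benjamini-Hochberg (independent
tests), or Benjamini-Yekutieli (dependent tests under unknown dependency).
Tests run on bootstrap-averaged per-unit values, never on pooled trials.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from . import __version__
from .core_data import SessionRecording
from .discriminability import (
    build_summary,
    compute_features,
    delta_psd_db,
)
from .core_data import select_analysis_trials
from .synthetic_session import SynthConfig, generate_session

logger = logging.getLogger("lfpdisc")

CORRECTIONS = {"bonferroni": "bonferroni", "bh_fdr": "fdr_bh", "by_fdr": "fdr_by"}

#: Exact tests below this per-group size, normal approximation above.
EXACT_N_MAX = 25


def _wilcoxon_signed_rank(diffs: np.ndarray) -> float:
    diffs = diffs[np.isfinite(diffs)]
    if len(diffs) < 2 or np.all(diffs == 0):
        return np.nan
    method = "exact" if len(diffs) <= EXACT_N_MAX else "approx"
    try:
        return float(stats.wilcoxon(diffs, method=method).pvalue)
    except ValueError:
        return np.nan


def _wilcoxon_rank_sum(a: np.ndarray, b: np.ndarray) -> float:
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if len(a) < 2 or len(b) < 2:
        return np.nan
    method = "exact" if min(len(a), len(b)) <= EXACT_N_MAX else "asymptotic"
    return float(stats.mannwhitneyu(a, b, alternative="two-sided",
                                    method=method).pvalue)


def corrected_test(
    comparisons: list,
    kind: str,
    correction: str = "by_fdr",
    alpha: float = 0.05,
    flip_negative: bool = False,
) -> pd.DataFrame:
    """Run one family of Wilcoxon tests with multiple-comparison correction.

    ``comparisons`` is a list of ``(id, data)`` where ``data`` is an array of
    paired differences (``kind='signed_rank'``, tested against zero) or a
    ``(sample_a, sample_b)`` tuple (``kind='rank_sum'``).  With
    ``flip_negative`` the absolute values are compared (the d'-magnitude
    convention).  Exact p-values are used for small samples, the normal
    approximation otherwise.  Undefined tests (all-zero differences, too few
    finite values) are reported with NaN p-values and excluded from the
    correction.
    """
    if kind not in ("signed_rank", "rank_sum"):
        raise ValueError("kind must be 'signed_rank' or 'rank_sum'")
    if correction not in CORRECTIONS:
        raise ValueError(f"correction must be one of {sorted(CORRECTIONS)}")
    ids, raw_p = [], []
    for comp_id, data in comparisons:
        if kind == "signed_rank":
            d = np.asarray(data, dtype=np.float64)
            if flip_negative:
                d = np.abs(d)
            p = _wilcoxon_signed_rank(d)
        else:
            a, b = (np.asarray(x, dtype=np.float64) for x in data)
            if flip_negative:
                a, b = np.abs(a), np.abs(b)
            p = _wilcoxon_rank_sum(a, b)
        ids.append(comp_id)
        raw_p.append(p)
    raw_p = np.asarray(raw_p)
    corrected = np.full_like(raw_p, np.nan)
    significant = np.zeros(len(raw_p), dtype=bool)
    ok = np.isfinite(raw_p)
    if ok.any():
        reject, p_corr, _, _ = multipletests(
            raw_p[ok], alpha=alpha, method=CORRECTIONS[correction])
        corrected[ok] = p_corr
        significant[ok] = reject
    return pd.DataFrame({
        "comparison": ids,
        "raw_p": raw_p,
        "corrected_p": corrected,
        "correction": correction,
        "significant": significant,
    })


def dprime_significance(
    units: dict,
    correction: str = "by_fdr",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Signed-rank tests of bootstrap-averaged d' against zero.

    ``units`` maps (measure, estimator, band, contrast, cue_type) to the
    per-unit d' array from :func:`~lfpdisc.discriminability.build_summary`.
    One correction family per (cue_type, contrast) — the analog of one
    summary panel, whose bars (measure x estimator x band) are dependent.
    """
    families: dict = {}
    for key, values in units.items():
        measure, estimator, band, contrast, cue_type = key
        families.setdefault((cue_type, contrast), []).append(
            ((measure, estimator, band), values))
    frames = []
    for (cue_type, contrast), comparisons in sorted(families.items()):
        df = corrected_test(comparisons, kind="signed_rank",
                            correction=correction, alpha=alpha)
        df.insert(0, "cue_type", cue_type)
        df.insert(1, "contrast", contrast)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

def run_pipeline(
    config: SynthConfig = None,
    session: SessionRecording = None,
    out_dir=None,
    n_boot: int = 50,
    seed: int = 0,
    correction: str = "by_fdr",
    include_pairs: bool = True,
) -> dict:
    """Generate/load -> select -> match -> measures -> band d' -> tests.

    Either a :class:`SynthConfig` (a session is generated) or an existing
    session must be given.  Returns a bundle with the d' summary frame, the
    per-unit d' values, the significance table, and per-condition delta-PSD
    (dB relative to the attend-out / target-out hit condition).  If
    ``out_dir`` is given, writes ``summary_dprime.csv``,
    ``significance.csv``, ``delta_psd_db.csv``, and ``run_meta.json``.
    """
    if (config is None) == (session is None):
        raise ValueError("pass exactly one of config or session")
    if session is None:
        session, _truth = generate_session(config)
    features = compute_features(session)
    summary, units = build_summary(
        session, n_boot=n_boot, seed=seed, include_pairs=include_pairs,
        features=features, return_units=True)
    tests = dprime_significance(units, correction=correction)

    # per-frequency PSD change relative to the attend/target-out hit condition
    psd_rows = []
    for rf_side in ("left", "right"):
        elec = session.electrodes_with_rf(rf_side)
        conds = select_analysis_trials(session, rf_side)
        for ref, others in (("AOVH", ("AIVH", "AIVM", "AOVM")),
                            ("TONH", ("TINH", "TINM", "TONM"))):
            if ref not in conds:
                continue
            for cond in others:
                db = delta_psd_db(features, conds[cond], conds[ref])[elec]
                for fi, f in enumerate(features.fine_freqs):
                    psd_rows.append({
                        "rf_side": rf_side, "condition": cond, "reference": ref,
                        "freq_hz": f, "delta_db": float(np.nanmean(db[:, fi])),
                    })
    delta_psd = pd.DataFrame(psd_rows)

    bundle = {"summary": summary, "units": units, "tests": tests,
              "delta_psd": delta_psd, "session": session}
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        summary.to_csv(out / "summary_dprime.csv", index=False)
        tests.to_csv(out / "significance.csv", index=False)
        delta_psd.to_csv(out / "delta_psd_db.csv", index=False)
        meta = {
            "lfpdisc_version": __version__,
            "seed": seed,
            "n_boot": n_boot,
            "correction": correction,
            "config": dataclasses.asdict(config) if config is not None else None,
        }
        (out / "run_meta.json").write_text(json.dumps(meta, indent=2))
        logger.info("pipeline outputs written to %s", out)
    return bundle
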