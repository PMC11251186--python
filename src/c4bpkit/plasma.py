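"""Plasma C4BP subunit stoichiometry from label-free proteomics.

Per-sample MaxLFQ intensities are anchored to absolute plasma
concentrations through a log–log linear regression against a panel of
reference proteins with known average plasma levels.  Converted molar
chain concentrations then yield the C4BPα/C4BPβ ratio — which falls in
the 6–7 band when only α6β1(+ProS) and α7β1(+ProS) variants co-occur
and rises above 7 when β-less 7α assemblies appear during acute-phase
inflammation — and the unbound ProS level, obtained by subtracting
C4BPβ (assumed ProS-saturated) from total ProS.  SEC co-elution and
iBAQ-based sample-purity profiling round out the stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

__all__ = [
    "RegressionFit",
    "fit_concentration_regression",
    "to_concentration",
    "to_molar",
    "subunit_ratio",
    "unbound_pros",
    "purity_profile",
    "sec_coelution",
    "EXPECTED_RATIO_BAND",
]

#: C4BPα/C4BPβ molar band consistent with exclusively β-containing
#: 6- and 7-α-chain variants.
EXPECTED_RATIO_BAND = (6.0, 7.0)


@dataclass
class RegressionFit:
    """Per-sample log10(LFQ) = a·log10(conc g/L) + b calibration."""

    a: float
    b: float
    r2: float
    n_used: int
    excluded: list[str]


def fit_concentration_regression(
    lfq: pd.Series,
    panel: dict[str, float],
) -> RegressionFit:
    """Fit one sample's LFQ intensities to known reference concentrations.

    ``lfq`` is the sample's protein -> MaxLFQ series; ``panel`` maps
    reference protein ids to known plasma concentrations (g/L).  Panel
    proteins without a quantified LFQ are excluded and logged; at least
    three usable points are required.
    """
    xs, ys, excluded = [], [], []
    for prot, conc in panel.items():
        if conc <= 0:
            raise ValueError(f"nonpositive panel concentration for {prot}")
        val = lfq.get(prot)
        if val is None or pd.isna(val) or val <= 0:
            excluded.append(prot)
            continue
        xs.append(np.log10(conc))
        ys.append(np.log10(val))
    if len(xs) < 3:
        raise ValueError(f"need >=3 quantified panel proteins, got {len(xs)}")
    if excluded:
        log.info("regression: excluded panel proteins without LFQ: %s", excluded)
    res = stats.linregress(xs, ys)
    return RegressionFit(
        a=float(res.slope), b=float(res.intercept), r2=float(res.rvalue**2),
        n_used=len(xs), excluded=excluded,
    )


def to_concentration(matrix: pd.DataFrame, fits: dict[str, RegressionFit] | None = None,
                     panel: dict[str, float] | None = None) -> pd.DataFrame:
    """Convert a samples × proteins LFQ matrix to g/L concentrations via
    per-sample fits: conc = 10^((log10 LFQ − b)/a).

    Either precomputed ``fits`` (sample -> RegressionFit) or a ``panel``
    to fit them from must be given.  Missing LFQ stays missing.
    """
    if fits is None:
        if panel is None:
            raise ValueError("provide fits or a reference panel")
        fits = {s: fit_concentration_regression(matrix.loc[s], panel) for s in matrix.index}
    out = pd.DataFrame(index=matrix.index, columns=matrix.columns, dtype=float)
    for s in matrix.index:
        f = fits[s]
        row = matrix.loc[s]
        with np.errstate(invalid="ignore", divide="ignore"):
            out.loc[s] = np.where(
                row > 0, 10 ** ((np.log10(row.astype(float)) - f.b) / f.a), np.nan
            )
    return out


def to_molar(conc_g_l: pd.DataFrame, mw_kda: dict[str, float]) -> pd.DataFrame:
    """Convert g/L concentrations to mol/L using chain molecular weights
    (kDa); proteins without an MW entry are dropped."""
    cols = [c for c in conc_g_l.columns if c in mw_kda]
    out = conc_g_l[cols].copy()
    for c in cols:
        out[c] = out[c] / (mw_kda[c] * 1000.0)
    return out


def subunit_ratio(
    molar: pd.DataFrame,
    alpha: str = "C4BPA",
    beta: str = "C4BPB",
    band: tuple[float, float] = EXPECTED_RATIO_BAND,
) -> pd.DataFrame:
    """Per-sample molar C4BPα/C4BPβ ratio with band membership flags.

    ``in_expected_range`` marks ratios inside [6, 7] (pure β-variant
    co-occurrence); ``variation_flag`` marks ratios above 7 (isoform
    variation — β-less species present).  Samples with missing or zero β
    yield a missing ratio with a warning.
    """
    lo, hi = band
    rows = []
    for s in molar.index:
        a_val = molar.at[s, alpha] if alpha in molar.columns else np.nan
        b_val = molar.at[s, beta] if beta in molar.columns else np.nan
        if pd.isna(a_val) or pd.isna(b_val) or b_val == 0:
            log.warning("subunit_ratio: undefined ratio for sample %s", s)
            ratio = np.nan
        else:
            ratio = a_val / b_val
        rows.append(
            {
                "sample": s,
                "ratio_alpha_beta": ratio,
                "in_expected_range": bool(lo <= ratio <= hi) if np.isfinite(ratio) else False,
                "variation_flag": bool(ratio > hi) if np.isfinite(ratio) else False,
            }
        )
    return pd.DataFrame(rows).set_index("sample")


def unbound_pros(molar: pd.DataFrame, pros: str = "PROS1", beta: str = "C4BPB") -> pd.Series:
    """Unbound ProS = max(0, [ProS] − [C4BPβ]) molar, assuming β-chains
    are ProS-saturated; negative intermediates are clamped and logged."""
    diff = molar[pros] - molar[beta]
    neg = diff < 0
    if neg.any():
        log.warning("unbound_pros: clamped negative values for samples %s", list(molar.index[neg]))
    return diff.clip(lower=0.0).rename("unbound_pros_m")


def purity_profile(
    ibaq: pd.Series,
    contaminants: set[str] | None = None,
    min_percent: float = 1.0,
) -> pd.Series:
    """iBAQ-based composition profile of a purified sample.

    Contaminant-flagged groups are dropped, the C4 isotypes C4A and C4B
    are merged as "C4b", values are normalized to 100 %, and groups
    strictly above ``min_percent`` are reported with the remainder
    folded into "other".
    """
    vals = ibaq.drop(labels=list(contaminants or ()), errors="ignore").astype(float)
    merged: dict[str, float] = {}
    for prot, v in vals.items():
        key = "C4b" if prot in ("C4A", "C4B") else prot
        merged[key] = merged.get(key, 0.0) + v
    total = sum(merged.values())
    if total <= 0:
        raise ValueError("no positive iBAQ values")
    pct = {k: 100.0 * v / total for k, v in merged.items()}
    kept = {k: v for k, v in pct.items() if v > min_percent}
    other = 100.0 - sum(kept.values())
    out = dict(sorted(kept.items(), key=lambda kv: -kv[1]))
    if other > 1e-12:
        out["other"] = other
    return pd.Series(out, name="percent")


def sec_coelution(profiles: pd.DataFrame, window: int = 3) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Smooth SEC elution profiles and score pairwise co-elution.

    ``profiles`` is long-format (protein, replicate, fraction,
    intensity).  Triplicates are summed per fraction, smoothed by a
    centered rolling mean (edges use the available fractions), and the
    replicate SD is smoothed the same way.  The co-elution score of a
    protein pair is the Pearson correlation of their smoothed profiles.

    Returns (smoothed wide DataFrame fraction × protein with columns
    also for ``<protein>_sd``, pairwise correlation DataFrame).
    """
    summed = profiles.pivot_table(
        index="fraction", columns="protein", values="intensity", aggfunc="sum"
    ).sort_index()
    sd = profiles.pivot_table(
        index="fraction", columns="protein", values="intensity", aggfunc="std"
    ).sort_index()
    smooth = summed.rolling(window, center=True, min_periods=1).mean()
    smooth_sd = sd.rolling(window, center=True, min_periods=1).mean()
    smooth_sd.columns = [f"{c}_sd" for c in smooth_sd.columns]
    corr = smooth.corr(method="pearson")
    return pd.concat([smooth, smooth_sd], axis=1), corr
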