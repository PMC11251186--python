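"""Site-resolved N-glycosylation profiling from glycopeptide PSM tables.

PSM tables (one row per peptide-spectrum match with a protein, glycosite,
glycan composition — empty for unoccupied peptides — search score and
|log prob|) are confidence-filtered, grouped per site, and quantified by
PSM counting.  Per-site proportions, the dominant glycoform, and a flag
for sites with substantial unoccupancy feed the complex-mass arithmetic
downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .masscalc import GlycanComposition

log = logging.getLogger(__name__)

__all__ = ["SiteProfile", "filter_psms", "site_profiles", "sites_summary", "export_glycoforms"]

REQUIRED_COLUMNS = ("protein", "site", "composition", "score", "log_prob")

#: Confidence filter defaults: search score strictly above 150 and
#: |log probability| strictly above 1.5.
DEFAULT_MIN_SCORE = 150.0
DEFAULT_MIN_LOG_PROB = 1.5

#: A site is flagged when strictly more than this fraction of its PSMs
#: is unoccupied.
HIGH_UNOCCUPIED_THRESHOLD = 0.20


def _is_unoccupied(comp) -> bool:
    if comp is None or (isinstance(comp, float) and pd.isna(comp)):
        return True
    return str(comp).strip() in ("", "none", "-", "(-)")


def filter_psms(
    table: pd.DataFrame,
    min_score: float = DEFAULT_MIN_SCORE,
    min_log_prob: float = DEFAULT_MIN_LOG_PROB,
) -> pd.DataFrame:
    """Keep PSMs with score > min_score and |log_prob| > min_log_prob
    (both strict)."""
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise KeyError(f"PSM table lacks required columns: {missing}")
    mask = (table["score"] > min_score) & (table["log_prob"].abs() > min_log_prob)
    return table.loc[mask].reset_index(drop=True)


@dataclass
class SiteProfile:
    protein: str
    site: int
    n_psm: int
    proportions: dict[str, float]  # composition key (or "unoccupied") -> fraction
    unoccupied_fraction: float
    dominant: GlycanComposition | None
    high_unoccupied_flag: bool


def _dominant_composition(occupied_counts: dict[str, int]) -> GlycanComposition | None:
    """Most abundant occupied composition; ties resolved toward higher
    sialylation (NeuAc count), then lexicographic key."""
    if not occupied_counts:
        return None
    parsed = {k: GlycanComposition.parse(k) for k in occupied_counts}
    best = max(
        occupied_counts,
        key=lambda k: (occupied_counts[k], parsed[k].n_NeuAc, [-ord(c) for c in k]),
    )
    return parsed[best]


def site_profiles(filtered: pd.DataFrame) -> list[SiteProfile]:
    """Group PSMs by (protein, site) and quantify composition proportions
    by PSM counts, including the unoccupied fraction."""
    profiles = []
    for (protein, site), grp in filtered.groupby(["protein", "site"], sort=True):
        n = len(grp)
        counts: dict[str, int] = {}
        n_unocc = 0
        for comp in grp["composition"]:
            if _is_unoccupied(comp):
                n_unocc += 1
            else:
                key = GlycanComposition.parse(str(comp)).key
                counts[key] = counts.get(key, 0) + 1
        props = {k: c / n for k, c in sorted(counts.items())}
        unocc = n_unocc / n
        if n_unocc:
            props["unoccupied"] = unocc
        profiles.append(
            SiteProfile(
                protein=str(protein),
                site=int(site),
                n_psm=n,
                proportions=props,
                unoccupied_fraction=unocc,
                dominant=_dominant_composition(counts),
                high_unoccupied_flag=unocc > HIGH_UNOCCUPIED_THRESHOLD,
            )
        )
    return profiles


def sites_summary(profiles: list[SiteProfile]) -> dict[str, int]:
    """Number of distinct glycosites with at least one occupied PSM,
    per protein."""
    out: dict[str, int] = {}
    for p in profiles:
        if p.dominant is not None:
            out[p.protein] = out.get(p.protein, 0) + 1
    return out


def export_glycoforms(profiles: list[SiteProfile]) -> dict[str, dict[int, GlycanComposition]]:
    """Per-chain map site -> dominant composition, for decorating chain
    masses with their most abundant experimentally detected glycans.
    Sites without any occupied PSM are omitted (logged)."""
    out: dict[str, dict[int, GlycanComposition]] = {}
    for p in profiles:
        if p.dominant is None:
            log.info("export_glycoforms: %s site %d has no occupied PSM; omitted", p.protein, p.site)
            continue
        out.setdefault(p.protein, {})[p.site] = p.dominant
    return out
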