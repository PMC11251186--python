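"""Cross-link confidence filtering and distance validation on
multi-chain coordinate models.

Chemical cross-links (DSS, K–K; DMTMM, E|D–K) identified by a
cross-link search are kept only when confidently and reproducibly
identified; surviving links are mapped onto a coordinate model.  Because
oligomeric assemblies contain several copies of the same chain, each
link is evaluated over *all* admissible chain-copy pairings; the
shortest Cα–Cα distance is reported together with any alternative
pairings within a 2 Å window, and links longer than the linker's
maximum span are flagged overlength.  Disulfide plausibility is checked
as an Sγ–Sγ distance cut.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "ModelCoordinates",
    "XLValidation",
    "link_class",
    "filter_links",
    "validate_links",
    "disulfide_check",
    "DEFAULT_MAX_LEN_A",
]

#: Maximum admissible Cα–Cα spans (Å) per linker chemistry.
DEFAULT_MAX_LEN_A = {"DSS": 30.0, "DMTMM": 25.0}

#: Window (Å) above the shortest pairing within which alternative
#: chain-copy pairings are reported.
ALTERNATE_WINDOW_A = 2.0

_LINK_COLUMNS = ("protein_a", "site_a", "protein_b", "site_b", "linker", "score", "replicate")

# Residue-type expectations per linker; violations warn, not fail,
# because site annotations may use precursor numbering offsets.
_DSS_RESIDUES = {"LYS"}
_DMTMM_ACIDIC = {"GLU", "ASP"}


def link_class(protein_a: str, site_a: int, protein_b: str, site_b: int) -> str:
    """Classify a link: self (identical protein+site on both ends),
    intra (same protein), or inter."""
    if protein_a == protein_b:
        return "self" if int(site_a) == int(site_b) else "intra"
    return "inter"


def filter_links(
    table: pd.DataFrame,
    min_score: float = 40.0,
    min_replicates: int = 2,
    n_replicates: int = 3,
) -> pd.DataFrame:
    """Confidence filter: keep links with score strictly above
    ``min_score`` identified in at least ``min_replicates`` of
    ``n_replicates`` experimental replicates.

    Rows are deduplicated by (endpoints, linker) with endpoint order
    canonicalized; the output carries one row per surviving link with
    its best score, replicate count and link class.
    """
    if min_replicates > n_replicates:
        raise ValueError("min_replicates cannot exceed n_replicates")
    missing = [c for c in _LINK_COLUMNS if c not in table.columns]
    if missing:
        raise KeyError(f"cross-link table lacks columns: {missing}")
    if table.empty:
        return table.iloc[0:0].copy()
    df = table.loc[table["score"] > min_score].copy()
    if df.empty:
        return df.iloc[0:0]

    def canon(row):
        a = (row["protein_a"], int(row["site_a"]))
        b = (row["protein_b"], int(row["site_b"]))
        return (a, b, row["linker"]) if a <= b else (b, a, row["linker"])

    df["_key"] = df.apply(canon, axis=1)
    rows = []
    for key, grp in df.groupby("_key", sort=True):
        reps = set(grp["replicate"])
        if len(reps) < min_replicates:
            continue
        (pa, ra), (pb, rb), linker = key
        rows.append(
            {
                "protein_a": pa,
                "site_a": ra,
                "protein_b": pb,
                "site_b": rb,
                "linker": linker,
                "score": float(grp["score"].max()),
                "n_replicates": len(reps),
                "link_class": link_class(pa, ra, pb, rb),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "protein_a", "site_a", "protein_b", "site_b",
            "linker", "score", "n_replicates", "link_class",
        ],
    )


@dataclass
class ModelCoordinates:
    """Cα (and, for cysteines, Sγ) coordinates per chain and residue."""

    ca: dict[str, dict[int, np.ndarray]]
    sg: dict[tuple[str, int], np.ndarray] = field(default_factory=dict)
    resnames: dict[tuple[str, int], str] = field(default_factory=dict)

    @classmethod
    def from_file(cls, path) -> "ModelCoordinates":
        """Read a PDB or mmCIF model with gemmi (first model only)."""
        import gemmi

        st = gemmi.read_structure(str(path))
        ca: dict[str, dict[int, np.ndarray]] = {}
        sg: dict[tuple[str, int], np.ndarray] = {}
        resnames: dict[tuple[str, int], str] = {}
        model = st[0]
        for chain in model:
            for res in chain:
                num = res.seqid.num
                resnames[(chain.name, num)] = res.name
                for atom in res:
                    pos = np.array([atom.pos.x, atom.pos.y, atom.pos.z])
                    if atom.name == "CA":
                        ca.setdefault(chain.name, {})[num] = pos
                    elif atom.name == "SG":
                        sg[(chain.name, num)] = pos
        return cls(ca=ca, sg=sg, resnames=resnames)


@dataclass
class XLValidation:
    protein_a: str
    site_a: int
    protein_b: str
    site_b: int
    linker: str
    link_class: str
    min_distance_a: float | None
    best_pairing: tuple[str, str] | None
    alternates: list[tuple[str, str, float]]  # pairings within the 2 Å window
    overlength: bool
    unmappable: bool


def _check_chemistry(model: ModelCoordinates, chain: str, res: int, linker: str, end: str) -> None:
    name = model.resnames.get((chain, res))
    if name is None:
        return
    if linker == "DSS" and name not in _DSS_RESIDUES:
        log.warning("DSS link endpoint %s:%d is %s, expected Lys/N-terminus", chain, res, name)
    elif linker == "DMTMM":
        ok = name in _DSS_RESIDUES | _DMTMM_ACIDIC
        if not ok:
            log.warning("DMTMM link endpoint %s:%d is %s, expected Lys/Glu/Asp", chain, res, name)


def validate_links(
    links: pd.DataFrame,
    model: ModelCoordinates,
    chain_map: dict[str, list[str]],
    max_len_a: dict[str, float] | None = None,
) -> list[XLValidation]:
    """Map each link onto the model over all chain-copy pairings.

    For self-links the two endpoints must sit on *different* physical
    copies; with a single copy present the link is unmappable (a
    residue cannot cross-link to itself at distance zero).
    """
    if not chain_map:
        raise ValueError("empty chain_map")
    caps = DEFAULT_MAX_LEN_A if max_len_a is None else max_len_a
    out = []
    for row in links.itertuples():
        pa, ra = row.protein_a, int(row.site_a)
        pb, rb = row.protein_b, int(row.site_b)
        linker = row.linker
        cls_ = link_class(pa, ra, pb, rb)
        candidates = []
        for ca_id, cb_id in itertools.product(chain_map.get(pa, []), chain_map.get(pb, [])):
            if cls_ == "self" and ca_id == cb_id:
                continue
            xa = model.ca.get(ca_id, {}).get(ra)
            xb = model.ca.get(cb_id, {}).get(rb)
            if xa is None or xb is None:
                continue
            _check_chemistry(model, ca_id, ra, linker, "a")
            _check_chemistry(model, cb_id, rb, linker, "b")
            candidates.append((ca_id, cb_id, float(np.linalg.norm(xa - xb))))
        if not candidates:
            out.append(
                XLValidation(pa, ra, pb, rb, linker, cls_, None, None, [], False, True)
            )
            continue
        candidates.sort(key=lambda t: t[2])
        ca_best, cb_best, dmin = candidates[0]
        alts = [
            (a, b, d)
            for a, b, d in candidates[1:]
            if d - dmin <= ALTERNATE_WINDOW_A
        ]
        out.append(
            XLValidation(
                pa, ra, pb, rb, linker, cls_,
                min_distance_a=dmin,
                best_pairing=(ca_best, cb_best),
                alternates=alts,
                overlength=dmin > caps[linker],
                unmappable=False,
            )
        )
    return out


def disulfide_check(
    model: ModelCoordinates,
    cys_pairs: list[tuple[tuple[str, int], tuple[str, int]]],
    threshold_a: float = 2.05,
) -> list[dict]:
    """Sγ–Sγ distance per cysteine pair; plausible iff strictly below the
    threshold (the bond-forming geometry cut)."""
    results = []
    for (ca_id, ra), (cb_id, rb) in cys_pairs:
        for cid, r in ((ca_id, ra), (cb_id, rb)):
            if (cid, r) not in model.sg:
                raise KeyError(f"no Sγ coordinate for residue {cid}:{r}")
        d = float(np.linalg.norm(model.sg[(ca_id, ra)] - model.sg[(cb_id, rb)]))
        results.append(
            {
                "pair": ((ca_id, ra), (cb_id, rb)),
                "distance_a": d,
                "plausible": d < threshold_a,
            }
        )
    return results
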