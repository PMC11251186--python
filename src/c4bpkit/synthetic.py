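"""Synthetic single-particle, glycoproteomic, cross-link and plasma data.

Every input the analysis pipeline consumes can be generated here with
the statistical structure the downstream stages assume, so the whole
chain is testable without instrument data.  Two kinds of serum presets
exist:

* ``observed`` presets parameterize the mass distributions directly by
  the resolved population means/SDs and weights (what an instrument
  histogram shows);
* the ``mechanistic`` preset draws latent particles from chain-level
  composition — an α7/α6 split ``f7`` and a ProS occupancy ``q`` of
  β-containing complexes — so that native and acidified measurements of
  the *same* population can be emulated and occupancy inference tested
  against ground truth.

All generators are deterministic given (parameters, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .single_particle import DEFAULT_CHARGE_FACTOR, PROTON_MASS_DA, IonEvent, MPEvent

__all__ = [
    "SerumPreset",
    "ChargeModel",
    "PRESETS",
    "occupancy_weights",
    "gen_cdms_events",
    "gen_mp_events",
    "gen_acidified",
    "gen_glyco_psms",
    "gen_xl_fixture",
    "gen_plasma_cohort",
    "gen_sec_profiles",
    "DEFAULT_GLYCO_SITE_TABLE",
    "REFERENCE_PANEL_G_PER_L",
]

# Chain masses (kDa) consistent with the four resolved complex peaks.
M_ALPHA_KDA = 72.9
M_BETA_KDA = 40.7
M_PROS_KDA = 79.8
FREE_PROS_SD_KDA = 6.0


def occupancy_weights(f7: float, q: float) -> tuple[float, float, float]:
    """Native complex-population weights (heavy, middle, light) implied by
    an α7 fraction ``f7`` and ProS occupancy ``q``.

    heavy  = α7β1+ProS          = f7·q
    middle = α7β1 ∪ α6β1+ProS   = f7·(1−q) + (1−f7)·q   (near-isobaric overlap)
    light  = α6β1               = (1−f7)·(1−q)
    """
    return f7 * q, f7 * (1 - q) + (1 - f7) * q, (1 - f7) * (1 - q)


@dataclass(frozen=True)
class SerumPreset:
    """Population parameters for a serum C4BP single-particle experiment.

    In ``observed`` mode the components (label -> mean/SD/weight) are the
    distribution; in ``mechanistic`` mode particles are drawn from
    (f7, q) with chain-mass arithmetic, and component entries are
    derived.
    """

    name: str
    mode: str  # "observed" | "mechanistic"
    component_masses: dict[str, float] = field(default_factory=dict)
    component_sds: dict[str, float] = field(default_factory=dict)
    component_weights: dict[str, float] = field(default_factory=dict)
    f7: float = 0.55
    q: float = 0.68
    heterogeneity_sd_kda: float = 20.0
    n_events: int = 5000
    pros_detection_efficiency: float = 1.0

    def __post_init__(self) -> None:
        if not 0 <= self.f7 <= 1 or not 0 <= self.q <= 1:
            raise ValueError("f7 and q must lie in [0, 1]")
        if self.n_events < 1:
            raise ValueError("n_events must be >= 1")
        if any(m <= 0 for m in self.component_masses.values()):
            raise ValueError("component masses must be positive")
        if any(s <= 0 for s in self.component_sds.values()):
            raise ValueError("component SDs must be positive")
        if self.mode == "observed":
            total = sum(self.component_weights.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"observed-mode weights must sum to 1, got {total}")
        elif self.mode != "mechanistic":
            raise ValueError(f"unknown mode {self.mode!r}")


def _observed(name, comps) -> SerumPreset:
    return SerumPreset(
        name=name,
        mode="observed",
        component_masses={k: v[0] for k, v in comps.items()},
        component_sds={k: v[1] for k, v in comps.items()},
        component_weights={k: v[2] for k, v in comps.items()},
    )


_A1, _A2, _A3 = occupancy_weights(0.55, 0.68)  # 0.374, 0.482, 0.144
# Acidified event mixture: every bound particle contributes one complex
# and one free-ProS event, so the free-ProS event fraction is q/(1+q).
_ACID_PROS_FRAC = 0.68 / 1.68
_MP_FREE_PROS_FRAC = 0.05

PRESETS: dict[str, SerumPreset] = {
    "SERUM-CDMS-NATIVE": _observed(
        "SERUM-CDMS-NATIVE",
        {
            "a7b1+ProS": (633.0, 22.0, _A1),
            "a7b1|a6b1+ProS": (553.0, 20.0, _A2),
            "a6b1": (481.0, 20.0, _A3),
        },
    ),
    "SERUM-CDMS-ACID": _observed(
        "SERUM-CDMS-ACID",
        {
            "a7b1": (551.0, 22.0, 0.55 * (1 - _ACID_PROS_FRAC)),
            "a6b1": (478.0, 23.0, 0.45 * (1 - _ACID_PROS_FRAC)),
            "ProS": (80.0, 6.0, _ACID_PROS_FRAC),
        },
    ),
    "SERUM-MP-NATIVE": _observed(
        "SERUM-MP-NATIVE",
        {
            "a7b1+ProS": (630.0, 29.0, _A1 * (1 - _MP_FREE_PROS_FRAC)),
            "a7b1|a6b1+ProS": (553.0, 22.0, _A2 * (1 - _MP_FREE_PROS_FRAC)),
            "a6b1": (487.0, 22.0, _A3 * (1 - _MP_FREE_PROS_FRAC)),
            "ProS": (68.0, 9.0, _MP_FREE_PROS_FRAC),
        },
    ),
    "MECHANISTIC": SerumPreset(name="MECHANISTIC", mode="mechanistic", f7=0.55, q=0.68),
}


def get_preset(name: str) -> SerumPreset:
    return PRESETS[name]


@dataclass(frozen=True)
class ChargeModel:
    """Mean ion charge scales as c·sqrt(mass in Da) (Rayleigh-limit-like),
    with Gaussian spread σz; charges are integral and >= 1."""

    c: float = 0.1
    sigma_z: float = 2.0


@dataclass(frozen=True)
class LatentParticles:
    """Ground-truth particle composition behind a mechanistic draw."""

    species: np.ndarray  # label per particle
    complex_mass_kda: np.ndarray
    pros_mass_kda: np.ndarray  # NaN where no ProS is bound

    @property
    def total_mass_kda(self) -> np.ndarray:
        return self.complex_mass_kda + np.nan_to_num(self.pros_mass_kda)

    @property
    def pros_bound(self) -> np.ndarray:
        return ~np.isnan(self.pros_mass_kda)


def _sample_mechanistic(preset: SerumPreset, n: int, rng: np.random.Generator) -> LatentParticles:
    m7 = 7 * M_ALPHA_KDA + M_BETA_KDA  # 551.0
    m6 = 6 * M_ALPHA_KDA + M_BETA_KDA  # 478.1
    # Complex-part SD chosen so the bound species' total SD equals the
    # preset heterogeneity SD.
    sd_c = np.sqrt(max(preset.heterogeneity_sd_kda**2 - FREE_PROS_SD_KDA**2, 1.0))
    is7 = rng.random(n) < preset.f7
    bound = rng.random(n) < preset.q
    cmass = rng.normal(np.where(is7, m7, m6), sd_c)
    cmass = np.abs(cmass)  # truncation at 0; never triggered at these params
    pmass = np.where(bound, rng.normal(M_PROS_KDA, FREE_PROS_SD_KDA, n), np.nan)
    species = np.where(is7, "a7b1", "a6b1").astype(object)
    species[bound] = species[bound] + "+ProS"
    return LatentParticles(np.asarray(species, dtype=str), cmass, pmass)


def _sample_observed(preset: SerumPreset, n: int, rng: np.random.Generator):
    labels = list(preset.component_masses)
    w = np.array([preset.component_weights[k] for k in labels])
    idx = rng.choice(len(labels), size=n, p=w / w.sum())
    means = np.array([preset.component_masses[k] for k in labels])[idx]
    sds = np.array([preset.component_sds[k] for k in labels])[idx]
    masses = np.abs(rng.normal(means, sds))
    return np.array(labels, dtype=str)[idx], masses


def _ionize(
    masses_kda: np.ndarray,
    rng: np.random.Generator,
    charge_model: ChargeModel,
    sigma_i: float,
    factor_k: float = DEFAULT_CHARGE_FACTOR,
) -> list[IonEvent]:
    mass_da = masses_kda * 1000.0
    z_mean = charge_model.c * np.sqrt(mass_da)
    z = np.floor(rng.normal(z_mean, charge_model.sigma_z) + 0.5) if charge_model.sigma_z > 0 else np.floor(z_mean + 0.5)
    z = np.maximum(z, 1.0)
    mz = (mass_da + z * PROTON_MASS_DA) / z
    # sigma_i is expressed in charge equivalents; divide by the factor to
    # put it on the normalized-intensity scale.
    inten = z / factor_k
    if sigma_i > 0:
        inten = inten + rng.normal(0.0, sigma_i, size=z.shape) / factor_k
    return [IonEvent(float(m), float(i)) for m, i in zip(mz, np.maximum(inten, 1e-9))]


def gen_cdms_events(
    preset: SerumPreset | str,
    n_events: int | None = None,
    seed: int = 0,
    charge_model: ChargeModel = ChargeModel(),
    sigma_i: float = 0.05,
) -> list[IonEvent]:
    """Generate raw CDMS ion events (m/z, normalized intensity) for a preset.

    ``sigma_i`` is Gaussian noise on the *charge-equivalent* intensity
    (charges); with sigma_i=0 and sigma_z=0 the calibration chain inverts
    events to their drawn masses exactly.
    """
    if isinstance(preset, str):
        preset = get_preset(preset)
    n = n_events if n_events is not None else preset.n_events
    if n < 1:
        raise ValueError("n_events must be >= 1")
    rng = np.random.default_rng(seed)
    if preset.mode == "mechanistic":
        masses = _sample_mechanistic(preset, n, rng).total_mass_kda
    else:
        _, masses = _sample_observed(preset, n, rng)
    return _ionize(masses, rng, charge_model, sigma_i)


def gen_acidified(
    preset: SerumPreset | str,
    n_events: int | None = None,
    seed: int = 0,
    charge_model: ChargeModel = ChargeModel(),
    sigma_i: float = 0.05,
) -> list[IonEvent]:
    """Acidified counterpart of a mechanistic native draw.

    The same latent particle population is drawn (same preset, seed and
    particle count as :func:`gen_cdms_events`), then every ProS-bound
    particle dissociates into its complex plus one free-ProS event.
    Free-ProS events are retained with probability
    ``pros_detection_efficiency``.
    """
    if isinstance(preset, str):
        preset = get_preset(preset)
    if preset.mode != "mechanistic":
        raise ValueError("acidification requires a mechanistic preset (latent composition)")
    n = n_events if n_events is not None else preset.n_events
    rng = np.random.default_rng(seed)
    latent = _sample_mechanistic(preset, n, rng)
    pros = latent.pros_mass_kda[latent.pros_bound]
    if preset.pros_detection_efficiency < 1.0:
        keep = rng.random(pros.size) < preset.pros_detection_efficiency
        pros = pros[keep]
    masses = np.concatenate([latent.complex_mass_kda, pros])
    return _ionize(masses, rng, charge_model, sigma_i)


def latent_truth(preset: SerumPreset | str, n_events: int, seed: int) -> LatentParticles:
    """Expose the latent particle draw for a mechanistic preset (ground truth
    for round-trip tests)."""
    if isinstance(preset, str):
        preset = get_preset(preset)
    if preset.mode != "mechanistic":
        raise ValueError("latent truth exists only for mechanistic presets")
    return _sample_mechanistic(preset, n_events, np.random.default_rng(seed))


def gen_mp_events(
    preset: SerumPreset | str,
    n_events: int | None = None,
    seed: int = 0,
    slope: float = 2e-5,
    intercept: float = 1e-4,
    noise_sd_kda: float = 3.0,
    include_calibrants: bool = True,
    calibrant_masses: tuple[float, ...] = (73.0, 149.0, 483.0, 800.0),
    n_per_calibrant: int = 200,
) -> tuple[list[MPEvent], pd.DataFrame]:
    """Generate MP contrast events plus a calibrant block.

    contrast = slope·mass + intercept + N(0, slope·noise_sd_kda).  The
    calibrant block holds replicate landing events at exactly the ladder
    masses (columns mass_kda, contrast); it is empty when
    ``include_calibrants`` is false.
    """
    if slope <= 0:
        raise ValueError("slope must be positive")
    if isinstance(preset, str):
        preset = get_preset(preset)
    n = n_events if n_events is not None else preset.n_events
    rng = np.random.default_rng(seed)
    if preset.mode == "mechanistic":
        masses = _sample_mechanistic(preset, n, rng).total_mass_kda
    else:
        _, masses = _sample_observed(preset, n, rng)
    sigma_c = slope * noise_sd_kda
    contrasts = slope * masses + intercept + (rng.normal(0, sigma_c, n) if sigma_c > 0 else 0.0)
    events = [MPEvent(float(c)) for c in contrasts]
    if include_calibrants:
        cm = np.repeat(np.asarray(calibrant_masses, dtype=float), n_per_calibrant)
        cc = slope * cm + intercept + (rng.normal(0, sigma_c, cm.size) if sigma_c > 0 else 0.0)
        calib = pd.DataFrame({"mass_kda": cm, "contrast": cc})
    else:
        calib = pd.DataFrame(columns=["mass_kda", "contrast"])
    return events, calib


# ---------------------------------------------------------------------------
# Glycopeptide PSM tables
# ---------------------------------------------------------------------------

# (protein, site) -> (unoccupied probability, {composition: relative weight}).
# Biantennary complex glycans with one or two sialic acids dominate every
# site except ProS N509, which carries triantennary sialylated glycans.
_BIANTENNARY = {
    "HexNAc4Hex5NeuAc2": 0.36,
    "HexNAc4Hex5NeuAc1": 0.33,
    "HexNAc4Hex5": 0.11,
    "HexNAc4Hex5dHex1NeuAc1": 0.10,
    "HexNAc3Hex4NeuAc1": 0.10,
}
_TRIANTENNARY = {
    "HexNAc5Hex6NeuAc3": 0.38,
    "HexNAc5Hex6NeuAc2": 0.34,
    "HexNAc4Hex5NeuAc2": 0.16,
    "HexNAc5Hex6NeuAc1": 0.12,
}

DEFAULT_GLYCO_SITE_TABLE: list[tuple[str, int, float, dict[str, float]]] = [
    ("C4BPa", 221, 0.25, _BIANTENNARY),
    ("C4BPa", 506, 0.05, _BIANTENNARY),
    ("C4BPa", 528, 0.25, _BIANTENNARY),
    ("C4BPb", 64, 0.05, _BIANTENNARY),
    ("C4BPb", 71, 0.25, _BIANTENNARY),
    ("C4BPb", 98, 0.05, _BIANTENNARY),
    ("C4BPb", 117, 0.05, _BIANTENNARY),
    ("C4BPb", 154, 0.05, _BIANTENNARY),
    ("ProS", 499, 0.05, _BIANTENNARY),
    ("ProS", 509, 0.05, _TRIANTENNARY),
    ("ProS", 530, 0.05, _BIANTENNARY),
]


def gen_glyco_psms(
    site_table: list[tuple[str, int, float, dict[str, float]]] | None = None,
    n_psm_per_site: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """Generate a glycopeptide PSM table (protein, site, composition,
    score, log_prob).

    Unoccupied PSMs carry an empty composition.  Scores ~ U(100, 400) and
    |log prob| ~ U(0.5, 4), so downstream confidence filtering thins each
    site without biasing its composition proportions.
    """
    table = DEFAULT_GLYCO_SITE_TABLE if site_table is None else site_table
    rng = np.random.default_rng(seed)
    rows = []
    for protein, site, p_unocc, comps in table:
        if n_psm_per_site <= 0:
            continue
        names = list(comps)
        w = np.array([comps[k] for k in names], dtype=float)
        w /= w.sum()
        for _ in range(n_psm_per_site):
            unocc = rng.random() < p_unocc
            comp = "" if unocc else names[rng.choice(len(names), p=w)]
            rows.append(
                {
                    "protein": protein,
                    "site": site,
                    "composition": comp,
                    "score": float(rng.uniform(100, 400)),
                    "log_prob": float(rng.uniform(0.5, 4.0)),
                }
            )
    return pd.DataFrame(rows, columns=["protein", "site", "composition", "score", "log_prob"])


# ---------------------------------------------------------------------------
# Cross-link fixture
# ---------------------------------------------------------------------------

def _xl_coordinates() -> dict[str, dict[int, dict[str, tuple[float, float, float]]]]:
    """Toy coordinate model: protein ProtA present as two copies (chains
    A and B), protein ProtB as chain C, Cα atoms on a known grid plus Sγ
    atoms for two cysteine pairs."""
    return {
        "A": {
            5: {"CA": (0.0, 0.0, 0.0)},
            10: {"CA": (10.0, 0.0, 0.0)},
            15: {"CA": (20.0, 0.0, 0.0)},
            20: {"CA": (30.0, 1.0, 0.0), "SG": (30.0, 0.0, 0.0)},
        },
        "B": {
            5: {"CA": (0.0, 0.0, 12.0)},
            10: {"CA": (30.0, 0.0, 0.0)},
            15: {"CA": (20.0, 0.0, 12.0)},
            20: {"CA": (50.0, 1.0, 0.0), "SG": (50.0, 0.0, 0.0)},
        },
        "C": {
            8: {"CA": (0.0, 0.0, 47.0)},
            12: {"CA": (30.0, 1.0, 2.03), "SG": (30.0, 0.0, 2.03)},
            18: {"CA": (50.0, 1.0, 2.10), "SG": (50.0, 0.0, 2.10)},
        },
    }


_XL_RESNAMES = {5: "LYS", 10: "LYS", 15: "GLU", 20: "CYS", 8: "LYS", 12: "CYS", 18: "CYS"}

XL_CHAIN_MAP = {"ProtA": ["A", "B"], "ProtB": ["C"]}


def _write_pdb(coords, path) -> None:
    import gemmi

    st = gemmi.Structure()
    st.name = "synthetic cross-link fixture"
    model = gemmi.Model("1")
    for chain_id, residues in coords.items():
        chain = gemmi.Chain(chain_id)
        for resnum in sorted(residues):
            res = gemmi.Residue()
            res.name = _XL_RESNAMES[resnum]
            res.seqid = gemmi.SeqId(resnum, " ")
            for aname, xyz in residues[resnum].items():
                atom = gemmi.Atom()
                atom.name = aname
                atom.element = gemmi.Element("S" if aname == "SG" else "C")
                atom.pos = gemmi.Position(*xyz)
                res.add_atom(atom)
            chain.add_residue(res)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


def _min_pair_distance(coords, chain_map, pa, ra, pb, rb) -> float | None:
    """Brute-force minimum Cα–Cα distance over chain-copy pairings (the
    fixture's ground truth); self-links exclude identical copies."""
    best = None
    for ca in chain_map[pa]:
        for cb in chain_map[pb]:
            if pa == pb and ra == rb and ca == cb:
                continue
            if ra not in coords[ca] or rb not in coords[cb]:
                continue
            xa = np.asarray(coords[ca][ra]["CA"])
            xb = np.asarray(coords[cb][rb]["CA"])
            d = float(np.linalg.norm(xa - xb))
            best = d if best is None or d < best else best
    return best


def gen_xl_fixture(seed: int, out_dir) -> dict:
    """Write a synthetic cross-link fixture: a minimal PDB model, a
    cross-link TSV and a JSON manifest of ground-truth distances.

    The link table exercises the confidence filter (scores straddling 40,
    replicate sets of size 1–3), a between-copy self-link, an overlength
    DSS link at 35 Å and an unmappable endpoint.
    """
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    coords = _xl_coordinates()
    model_path = out / "model.pdb"
    _write_pdb(coords, model_path)

    # (pa, ra, pb, rb, linker, replicates, score_low, score_high)
    link_defs = [
        ("ProtA", 5, "ProtA", 15, "DMTMM", (1, 2, 3), 60, 100),  # intra, 20 Å
        ("ProtA", 10, "ProtA", 10, "DSS", (1, 3), 45, 90),       # self, copies 20 Å apart
        ("ProtA", 5, "ProtB", 8, "DSS", (1, 2), 50, 95),         # inter, min 35 Å -> overlength
        ("ProtA", 5, "ProtA", 10, "DSS", (2, 3), 41, 80),        # intra, 10 Å
        ("ProtA", 99, "ProtB", 8, "DSS", (1, 2, 3), 55, 85),     # unmappable endpoint
        ("ProtA", 5, "ProtB", 8, "DMTMM", (2,), 70, 99),         # single replicate -> dropped
        ("ProtA", 10, "ProtA", 15, "DSS", (1, 2, 3), 20, 40),    # score <= 40 -> dropped
    ]
    rows = []
    for pa, ra, pb, rb, linker, reps, lo, hi in link_defs:
        for rep in reps:
            rows.append(
                {
                    "protein_a": pa,
                    "site_a": ra,
                    "protein_b": pb,
                    "site_b": rb,
                    "linker": linker,
                    "score": float(rng.uniform(lo, hi)),
                    "replicate": rep,
                }
            )
    links = pd.DataFrame(rows)
    links_path = out / "links.tsv"
    links.to_csv(links_path, sep="\t", index=False)

    manifest = {}
    for pa, ra, pb, rb, linker, *_ in link_defs:
        key = f"{pa}:{ra}--{pb}:{rb}:{linker}"
        d = _min_pair_distance(coords, XL_CHAIN_MAP, pa, ra, pb, rb)
        manifest[key] = {"min_distance_A": d}
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1))
    return {
        "model": model_path,
        "links": links_path,
        "manifest": manifest_path,
        "chain_map": XL_CHAIN_MAP,
        "cys_pairs": [(("A", 20), ("C", 12)), (("B", 20), ("C", 18))],
    }


# ---------------------------------------------------------------------------
# Plasma cohort
# ---------------------------------------------------------------------------

#: Synthetic "known reported average" plasma concentrations (g/L) for the
#: 22-protein reference panel (literature-plausible values; the real
#: reference values are supplied by the user for real data).
REFERENCE_PANEL_G_PER_L: dict[str, float] = {
    "A2M": 1.5, "B2M": 0.002, "C1R": 0.05, "C2": 0.025, "C6": 0.045,
    "C9": 0.06, "CFP": 0.025, "CP": 0.3, "F10": 0.01, "F12": 0.03,
    "F2": 0.1, "F7": 0.0005, "F8": 0.0001, "F9": 0.005, "HP": 1.0,
    "KLKB1": 0.05, "MB": 0.00005, "MBL2": 0.001, "SERPINA1": 1.4,
    "TFRC": 0.001, "TTR": 0.25, "VWF": 0.01,
}

#: Chain molecular weights (kDa) for molar conversion of the C4BP system.
PLASMA_MW_KDA = {"C4BPA": M_ALPHA_KDA, "C4BPB": M_BETA_KDA, "PROS1": M_PROS_KDA, "CRP": 25.0}

_CRP_HEALTHY_G_L = 0.001
_CRP_ACUTE_G_L = 0.10
#: Clinically conventional acute-phase CRP cut (10 mg/L).
CRP_ACUTE_THRESHOLD_G_L = 0.01


def gen_plasma_cohort(
    n_donors: int = 2,
    timepoints: int = 8,
    scenario: str = "healthy",
    seed: int = 0,
    sigma: float = 0.05,
    a: float = 1.0,
    b: float = 9.0,
    complex_conc_m: float = 1.75e-7,
    free_pros_m: float = 1.2e-7,
    acute_timepoints: tuple[int, ...] = (1, 6),
    acute_7a_fraction: float = 0.5,
) -> dict:
    """Simulate a longitudinal plasma LFQ cohort.

    Healthy donors carry equimolar α6β1+ProS and α7β1+ProS (total complex
    concentration ``2·complex_conc_m``); in the ``acute`` scenario the
    listed timepoints replace a fraction ``acute_7a_fraction`` of
    complexes by the β-less 7α species and spike CRP.  Chain
    concentrations map to MaxLFQ intensities through
    log10(LFQ) = a·log10(conc g/L) + b + N(0, σ).

    Returns dict with keys ``lfq`` (samples × proteins DataFrame),
    ``panel`` (reference concentrations, g/L), ``truth`` (per-sample
    ground-truth molar table) and ``mw_kda``.
    """
    rng = np.random.default_rng(seed)
    samples, truth_rows, lfq_rows = [], [], []
    for d in range(n_donors):
        for t in range(timepoints):
            name = f"D{d + 1}_T{t}"
            samples.append(name)
            is_acute = scenario == "acute" and t in acute_timepoints
            total_complex = 2 * complex_conc_m
            phi = acute_7a_fraction if is_acute else 0.0
            c_beta_variants = total_complex * (1 - phi)  # split equally α6β1+ProS / α7β1+ProS
            c6, c7 = c_beta_variants / 2, c_beta_variants / 2
            c7a = total_complex * phi
            alpha = 6 * c6 + 7 * c7 + 7 * c7a
            beta = c6 + c7
            pros_total = c6 + c7 + free_pros_m  # bound (=β occupancy 1) + free
            crp = (_CRP_ACUTE_G_L if is_acute else _CRP_HEALTHY_G_L) / (
                PLASMA_MW_KDA["CRP"] * 1000.0
            )
            truth_rows.append(
                {
                    "sample": name,
                    "alpha_m": alpha,
                    "beta_m": beta,
                    "pros_total_m": pros_total,
                    "free_pros_m": free_pros_m,
                    "ratio_alpha_beta": alpha / beta,
                    "crp_m": crp,
                    "is_acute": is_acute,
                }
            )
            conc_g_l = {
                "C4BPA": alpha * PLASMA_MW_KDA["C4BPA"] * 1000.0,
                "C4BPB": beta * PLASMA_MW_KDA["C4BPB"] * 1000.0,
                "PROS1": pros_total * PLASMA_MW_KDA["PROS1"] * 1000.0,
                "CRP": crp * PLASMA_MW_KDA["CRP"] * 1000.0,
            }
            conc_g_l.update(REFERENCE_PANEL_G_PER_L)
            row = {}
            for prot, c in conc_g_l.items():
                noise = rng.normal(0.0, sigma) if sigma > 0 else 0.0
                row[prot] = 10 ** (a * np.log10(c) + b + noise)
            lfq_rows.append(row)
    lfq = pd.DataFrame(lfq_rows, index=pd.Index(samples, name="sample"))
    truth = pd.DataFrame(truth_rows).set_index("sample")
    return {
        "lfq": lfq,
        "panel": dict(REFERENCE_PANEL_G_PER_L),
        "truth": truth,
        "mw_kda": dict(PLASMA_MW_KDA),
    }


def gen_sec_profiles(
    seed: int = 0,
    n_fractions: int = 40,
    noise: float = 0.05,
) -> pd.DataFrame:
    """Triplicate SEC elution profiles (long format: protein, replicate,
    fraction, intensity).

    C4BPα, C4BPβ and ProS share a high-molecular-weight co-elution peak;
    ProS has an additional late monomer peak, so its profile decorrelates
    from the chains that exist only complex-bound.
    """
    rng = np.random.default_rng(seed)
    frac = np.arange(n_fractions, dtype=float)

    def peak(center, width, height):
        return height * np.exp(-0.5 * ((frac - center) / width) ** 2)

    shapes = {
        "C4BPA": peak(12, 2.0, 100.0),
        "C4BPB": peak(12, 2.0, 30.0),
        "PROS1": peak(12, 2.0, 40.0) + peak(26, 2.5, 60.0),
    }
    rows = []
    for prot, shape in shapes.items():
        for rep in (1, 2, 3):
            vals = shape * (1 + rng.normal(0, noise, n_fractions))
            for f, v in zip(frac, np.maximum(vals, 0.0)):
                rows.append(
                    {"protein": prot, "replicate": rep, "fraction": int(f), "intensity": float(v)}
                )
    return pd.DataFrame(rows)
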