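"""Mass arithmetic for protein chains, N-glycans and C4BP complex species.

C4b-binding protein (C4BP) circulates as a family of higher-order
stoichiometric variants built from α-chains (~73 kDa glycosylated),
a single β-chain (~41 kDa) and, on β-containing variants, one
non-covalently bound protein S (ProS, ~80 kDa).  Because the
glycosylated α-chain and ProS are nearly isobaric, an observed particle
mass rarely maps to a unique (n_α, n_β, n_ProS) stoichiometry; this
module makes that ambiguity explicit by exhaustive enumeration over a
bounded stoichiometry lattice.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from pyteomics import mass as _pmass

__all__ = [
    "GlycanComposition",
    "ChainSpec",
    "ComplexSpecies",
    "MassAssignment",
    "glycan_mass",
    "chain_mass",
    "complex_mass",
    "assign_stoichiometry",
    "read_fasta_chains",
    "MECHANISTIC_CHAIN_MASSES_KDA",
]

# Dehydrated (glycosidic-bond) monosaccharide residue compositions.
_GLYCAN_FORMULAS = {
    "HexNAc": "C8H13NO5",
    "Hex": "C6H10O5",
    "dHex": "C6H10O4",
    "NeuAc": "C11H17NO8",
}

_GLYCAN_MONO = {k: _pmass.calculate_mass(formula=f) for k, f in _GLYCAN_FORMULAS.items()}
_GLYCAN_AVG = {
    k: _pmass.calculate_mass(formula=f, average=True) for k, f in _GLYCAN_FORMULAS.items()
}

#: Chain masses (kDa) consistent with the four resolved complex peaks:
#: α7β1 551.0, α6β1 478.1, +ProS shifts of 79.8.
MECHANISTIC_CHAIN_MASSES_KDA = {"C4BPa": 72.9, "C4BPb": 40.7, "ProS": 79.8}

# Fig-5-style shorthand: N=HexNAc, H=Hex, F=dHex (fucose), S=NeuAc.
_SHORT_TO_LONG = {"N": "HexNAc", "H": "Hex", "F": "dHex", "S": "NeuAc"}
_LONG_RE = re.compile(r"(HexNAc|Hex|dHex|NeuAc)(\d*)")
_SHORT_RE = re.compile(r"([NHFS])(\d*)")


@dataclass(frozen=True, order=True)
class GlycanComposition:
    """Counts of monosaccharide residues in an N-glycan composition."""

    n_HexNAc: int = 0
    n_Hex: int = 0
    n_dHex: int = 0
    n_NeuAc: int = 0

    def __post_init__(self) -> None:
        for name, n in self.as_dict().items():
            if n < 0 or int(n) != n:
                raise ValueError(f"negative or non-integer count for {name}: {n}")

    def as_dict(self) -> dict[str, int]:
        return {
            "HexNAc": self.n_HexNAc,
            "Hex": self.n_Hex,
            "dHex": self.n_dHex,
            "NeuAc": self.n_NeuAc,
        }

    def __add__(self, other: "GlycanComposition") -> "GlycanComposition":
        return GlycanComposition(
            self.n_HexNAc + other.n_HexNAc,
            self.n_Hex + other.n_Hex,
            self.n_dHex + other.n_dHex,
            self.n_NeuAc + other.n_NeuAc,
        )

    @property
    def key(self) -> str:
        """Serialized composition key, e.g. ``"HexNAc4Hex5NeuAc2"``."""
        parts = []
        for name, n in self.as_dict().items():
            if n:
                parts.append(f"{name}{n}")
        return "".join(parts) or "none"

    @classmethod
    def parse(cls, text: str) -> "GlycanComposition":
        """Parse either long (``HexNAc4Hex5NeuAc2``) or short (``N4H5S2``) notation."""
        text = text.strip()
        counts = dict.fromkeys(_GLYCAN_FORMULAS, 0)
        if text in ("", "none", "-", "(-)"):
            return cls()
        # Long tokens must be tried first: "Hex" is a prefix of "HexNAc".
        if any(tok in text for tok in _GLYCAN_FORMULAS):
            pat, mapper = _LONG_RE, {k: k for k in _GLYCAN_FORMULAS}
        else:
            pat, mapper = _SHORT_RE, _SHORT_TO_LONG
        pos = 0
        for m in pat.finditer(text):
            if m.start() != pos:
                raise ValueError(f"cannot parse glycan composition {text!r}")
            counts[mapper[m.group(1)]] += int(m.group(2) or 1)
            pos = m.end()
        if pos != len(text):
            raise ValueError(f"cannot parse glycan composition {text!r}")
        return cls(counts["HexNAc"], counts["Hex"], counts["dHex"], counts["NeuAc"])

    def __str__(self) -> str:  # pragma: no cover
        return self.key


def glycan_mass(comp: GlycanComposition, mode: str = "average") -> float:
    """Mass in Da of a glycan composition (dehydrated residue convention).

    The residues are summed as glycosidically bonded units; the mass of
    the attachment water stays with the peptide backbone.
    """
    table = {"monoisotopic": _GLYCAN_MONO, "average": _GLYCAN_AVG}[mode]
    return sum(table[name] * n for name, n in comp.as_dict().items())


@dataclass
class ChainSpec:
    """A protein chain given either as a mature sequence or a fixed mass.

    glycoforms maps glycosite residue number -> GlycanComposition; the
    glycan masses are added on top of the polypeptide (or fixed) mass.
    """

    chain_id: str
    sequence: str | None = None
    fixed_mass_kda: float | None = None
    glycoforms: dict[int, GlycanComposition] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.sequence is None) == (self.fixed_mass_kda is None):
            raise ValueError("exactly one of sequence / fixed_mass_kda must be set")
        if self.sequence is not None:
            for site in self.glycoforms:
                if not 1 <= site <= len(self.sequence):
                    raise ValueError(f"glycosite {site} outside sequence of {self.chain_id}")


def chain_mass(spec: ChainSpec, mode: str = "average") -> float:
    """Chain mass in kDa: polypeptide (residues + one water) or fixed mass,
    plus the masses of all attached glycans."""
    if spec.sequence is not None:
        base_da = _pmass.calculate_mass(sequence=spec.sequence, average=(mode == "average"))
    else:
        base_da = spec.fixed_mass_kda * 1000.0
    glyco_da = sum(glycan_mass(c, mode) for c in spec.glycoforms.values())
    return (base_da + glyco_da) / 1000.0


def _format_label(n_alpha: int, n_beta: int, n_pros: int) -> str:
    parts = []
    if n_alpha:
        parts.append(f"a{n_alpha}")
    if n_beta:
        parts.append(f"b{n_beta}")
    core = "".join(parts) or "apo"
    if n_pros:
        core += "+ProS" if n_pros == 1 else f"+{n_pros}ProS"
    return core


@dataclass(frozen=True)
class ComplexSpecies:
    """A C4BP assembly stoichiometry with its derived mass."""

    n_alpha: int
    n_beta: int
    n_pros: int
    label: str
    mass_kda: float

    @property
    def n_subunits(self) -> int:
        return self.n_alpha + self.n_beta + self.n_pros


def complex_mass(
    stoich: tuple[int, int, int],
    chain_masses: dict[str, float] = MECHANISTIC_CHAIN_MASSES_KDA,
) -> ComplexSpecies:
    """Mass of an (n_α, n_β, n_ProS) assembly as a linear combination of
    chain masses (kDa)."""
    n_alpha, n_beta, n_pros = stoich
    if n_alpha == n_beta == n_pros == 0:
        raise ValueError("all-zero stoichiometry")
    for key in ("C4BPa", "C4BPb", "ProS"):
        if key not in chain_masses:
            raise KeyError(f"chain mass map lacks {key}")
    m = (
        n_alpha * chain_masses["C4BPa"]
        + n_beta * chain_masses["C4BPb"]
        + n_pros * chain_masses["ProS"]
    )
    return ComplexSpecies(n_alpha, n_beta, n_pros, _format_label(n_alpha, n_beta, n_pros), m)


@dataclass
class MassAssignment:
    """Ranked stoichiometry candidates for one observed mass."""

    observed_kda: float
    sd_kda: float
    candidates: list[tuple[ComplexSpecies, float]]
    ambiguous: bool

    @property
    def best(self) -> ComplexSpecies | None:
        return self.candidates[0][0] if self.candidates else None


def assign_stoichiometry(
    observed_kda: float,
    sd_kda: float,
    chain_masses: dict[str, float] = MECHANISTIC_CHAIN_MASSES_KDA,
    bounds: tuple[int, int, int] = (8, 1, 1),
    k_sigma: float = 2.0,
) -> MassAssignment:
    """Enumerate the bounded stoichiometry lattice and rank candidates.

    Candidates are assemblies whose predicted mass lies within
    ``k_sigma * sd_kda`` of the observed mass, ranked by |error| with
    ties broken toward fewer subunits, then lexicographic label.  The
    assignment is flagged ambiguous when at least two candidates
    survive — the situation the near-isobaric α-chain/ProS pair creates
    for the middle native C4BP population.
    """
    if observed_kda <= 0:
        raise ValueError("observed mass must be positive")
    if not chain_masses:
        raise ValueError("empty chain-mass map")
    max_a, max_b, max_p = bounds
    if min(bounds) < 0:
        raise ValueError("bounds must be non-negative")
    tol = k_sigma * sd_kda
    cands: list[tuple[ComplexSpecies, float]] = []
    for na in range(max_a + 1):
        for nb in range(max_b + 1):
            for np_ in range(max_p + 1):
                if na == nb == np_ == 0:
                    continue
                sp = complex_mass((na, nb, np_), chain_masses)
                err = sp.mass_kda - observed_kda
                if abs(err) <= tol:
                    cands.append((sp, err))
    cands.sort(key=lambda ce: (abs(ce[1]), ce[0].n_subunits, ce[0].label))
    return MassAssignment(observed_kda, sd_kda, cands, ambiguous=len(cands) >= 2)


def read_fasta_chains(path) -> dict[str, ChainSpec]:
    """Read mature chain sequences from FASTA into ChainSpec objects."""
    from Bio import SeqIO

    chains = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        chains[rec.id] = ChainSpec(chain_id=rec.id, sequence=str(rec.seq))
    return chains
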