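"""Gaussian-mixture deconvolution of single-particle mass histograms.

The central analysis step: a mass histogram of co-occurring C4BP
assemblies is modeled as a k-component Gaussian mixture fitted by
expectation–maximization.  Component weights quantify isoform
abundances; comparing a native fit against an acidified fit of the same
serum resolves the near-isobaric overlap between α7β1 and α6β1+ProS and
yields the ProS occupancy of β-containing complexes in closed form.

Occupancy algebra.  Let the native complex populations (weights a1
heavy, a2 middle, a3 light, a1+a2+a3=1) be α7β1+ProS, the overlapping
{α7β1 ∪ α6β1+ProS}, and α6β1.  Acidification strips ProS, collapsing
the histogram onto α7β1 and α6β1 with the α7 fraction f7.  Writing x for
the α7β1 share of the middle native population:

    f7 = a1 + x                 (all α7 complexes end up in the acid heavy peak)
    pros_bound = a1 + (a2 − x)  = 2·a1 + a2 − f7

which is solvable without ever separating the overlapped pair directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .masscalc import MECHANISTIC_CHAIN_MASSES_KDA, MassAssignment, assign_stoichiometry

__all__ = [
    "MixtureModel",
    "IsoformQuant",
    "OccupancyEstimate",
    "ShiftReport",
    "fit_mixture",
    "quantify_isoforms",
    "resolve_overlap",
    "estimate_occupancy",
    "detect_shift",
]

_MIN_SD_KDA = 1e-3


@dataclass
class MixtureModel:
    """A fitted 1-D Gaussian mixture over particle masses (kDa).

    ``components`` are (mean, sd, weight) sorted by mean ascending.
    ``event_count_weights`` are the alternative abundance estimates from
    counting events assigned (by maximum responsibility) to each
    component within ±2σ of its mean, renormalized — i.e. comparing the
    single-particle events corresponding to each population rather than
    integrating the model.
    """

    components: list[tuple[float, float, float]]
    loglik: float
    bic: float
    n_events: int
    fit_window: tuple[float, float]
    seed: int
    event_count_weights: list[float] = field(default_factory=list)

    @property
    def k(self) -> int:
        return len(self.components)

    @property
    def means(self) -> np.ndarray:
        return np.array([c[0] for c in self.components])

    @property
    def sds(self) -> np.ndarray:
        return np.array([c[1] for c in self.components])

    @property
    def weights(self) -> np.ndarray:
        return np.array([c[2] for c in self.components])


def _em_1d(x: np.ndarray, k: int, max_iter: int, tol: float):
    n = x.size
    # Quantile-spaced initialization: deterministic and well spread.
    qs = (np.arange(k) + 0.5) / k
    mu = np.quantile(x, qs)
    sd = np.full(k, max(x.std(ddof=0) / k, _MIN_SD_KDA))
    w = np.full(k, 1.0 / k)
    prev_ll = -np.inf
    for _ in range(max_iter):
        log_pdf = stats.norm.logpdf(x[:, None], mu[None, :], sd[None, :]) + np.log(w)[None, :]
        m = log_pdf.max(axis=1, keepdims=True)
        lse = m[:, 0] + np.log(np.exp(log_pdf - m).sum(axis=1))
        ll = lse.sum()
        # EM guarantee: the log-likelihood never decreases.
        if ll < prev_ll - 1e-6:
            raise RuntimeError("EM log-likelihood decreased — numerical failure")
        resp = np.exp(log_pdf - lse[:, None])
        nk = resp.sum(axis=0)
        nk = np.maximum(nk, 1e-12)
        w = nk / n
        mu = (resp * x[:, None]).sum(axis=0) / nk
        var = (resp * (x[:, None] - mu[None, :]) ** 2).sum(axis=0) / nk
        sd = np.maximum(np.sqrt(var), _MIN_SD_KDA)
        if ll - prev_ll < tol and np.isfinite(prev_ll):
            prev_ll = ll
            break
        prev_ll = ll
    return mu, sd, w, prev_ll, resp


def fit_mixture(
    masses,
    k: int | str = "auto",
    window: tuple[float, float] | None = None,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-8,
    k_range: range = range(1, 7),
) -> MixtureModel:
    """Fit a k-component Gaussian mixture to mass events by EM.

    ``k="auto"`` scans ``k_range`` and selects the minimum-BIC model.
    Initialization is by quantile-spaced means, so the fit is
    deterministic for a given event set.
    """
    x = np.asarray([m.mass_kda if hasattr(m, "mass_kda") else float(m) for m in masses])
    lo, hi = window if window is not None else (float(x.min()), float(x.max()))
    if not hi > lo:
        raise ValueError("degenerate fit window")
    x = x[(x >= lo) & (x <= hi)]

    def fit_k(kk: int) -> MixtureModel:
        if x.size < 10 * kk:
            raise ValueError(f"need at least {10 * kk} events in window for k={kk}, got {x.size}")
        mu, sd, w, ll, resp = _em_1d(x, kk, max_iter, tol)
        order = np.argsort(mu)
        mu_o, sd_o, w_o = mu[order], sd[order], w[order]
        n_params = 3 * kk - 1
        bic = n_params * np.log(x.size) - 2 * ll
        # Event-count weights: hard-assign events by max responsibility,
        # keep those within ±2σ of their component mean, renormalize.
        hard = np.argmax(resp[:, order], axis=1)
        counts = np.zeros(kk)
        for j in range(kk):
            sel = (hard == j) & (np.abs(x - mu_o[j]) <= 2 * sd_o[j])
            counts[j] = sel.sum()
        ec = counts / counts.sum() if counts.sum() > 0 else np.full(kk, np.nan)
        return MixtureModel(
            components=[(float(m), float(s), float(ww)) for m, s, ww in zip(mu_o, sd_o, w_o)],
            loglik=float(ll),
            bic=float(bic),
            n_events=int(x.size),
            fit_window=(lo, hi),
            seed=seed,
            event_count_weights=[float(e) for e in ec],
        )

    if k == "auto":
        best = None
        for kk in k_range:
            if x.size < 10 * kk:
                break
            model = fit_k(kk)
            if best is None or model.bic < best.bic:
                best = model
        if best is None:
            raise ValueError("too few events for any candidate k")
        return best
    return fit_k(int(k))


@dataclass
class IsoformQuant:
    """Per-component isoform abundances with stoichiometry assignments."""

    weights: list[float]
    assignments: list[MassAssignment]
    labels: list[list[str]]
    ambiguous: list[bool]


def quantify_isoforms(
    model: MixtureModel,
    chain_masses: dict[str, float] = MECHANISTIC_CHAIN_MASSES_KDA,
    k_sigma: float = 2.0,
) -> IsoformQuant:
    """Turn mixture components into isoform abundances: each component's
    weight is its abundance and its mean is assigned a stoichiometry,
    propagating the assignment ambiguity."""
    weights, assigns, labels, amb = [], [], [], []
    for mean, sd, w in model.components:
        a = assign_stoichiometry(mean, sd, chain_masses, k_sigma=k_sigma)
        weights.append(w)
        assigns.append(a)
        labels.append([sp.label for sp, _ in a.candidates])
        amb.append(a.ambiguous)
    return IsoformQuant(weights=weights, assignments=assigns, labels=labels, ambiguous=amb)


@dataclass
class OccupancyEstimate:
    a1: float
    a2: float
    a3: float
    f7: float
    x: float  # inferred α7β1 share of the native middle population
    pros_bound: float
    feasible: bool


def resolve_overlap(a1: float, a2: float, a3: float, f7: float) -> OccupancyEstimate:
    """Closed-form resolution of the native middle-population overlap.

    Given native complex weights (a1 heavy, a2 middle, a3 light) and the
    acidified α7 fraction f7, the α7β1 share of the middle population is
    x = f7 − a1 and the ProS-bound fraction is 2·a1 + a2 − f7.  Inputs
    outside the feasible region (0 ≤ x ≤ a2) are clamped and flagged.
    """
    if abs(a1 + a2 + a3 - 1.0) > 1e-6:
        raise ValueError("native complex weights must sum to 1")
    if not 0 <= f7 <= 1:
        raise ValueError("f7 must lie in [0, 1]")
    x = f7 - a1
    feasible = -1e-9 <= x <= a2 + 1e-9
    x_clamped = min(max(x, 0.0), a2)
    pros = 2 * a1 + a2 - f7
    pros = min(max(pros, 0.0), 1.0)
    return OccupancyEstimate(a1, a2, a3, f7, x_clamped, pros, feasible)


def estimate_occupancy(
    native_masses,
    acidified_masses,
    complex_floor_kda: float = 200.0,
    seed: int = 0,
    weight_source: str = "event_counts",
    m_pros_kda: float = 79.8,
) -> OccupancyEstimate:
    """Estimate ProS occupancy from paired native/acidified mass events.

    Fits k=3 to native events above the complex floor (three complex
    populations) and k=2 to acidified events above the floor (the two
    ProS-stripped β-variants); f7 is the heavier acidified weight.
    ``weight_source`` selects between per-population event counts
    (default, matching quantification by counting single-particle
    events) and raw mixture weights; both are available on the models.

    The three native components are anchored to the expected population
    centers implied by the acidified fit (m6, the overlapped m7/m6+ProS
    pair, m7+ProS) by nearest mean, so that weights stay correctly
    attributed even when one population is nearly absent (extreme
    occupancies) and the unconstrained k=3 fit splits a single peak.
    """
    native = np.asarray([m.mass_kda if hasattr(m, "mass_kda") else float(m) for m in native_masses])
    acid = np.asarray(
        [m.mass_kda if hasattr(m, "mass_kda") else float(m) for m in acidified_masses]
    )
    if native.size == 0 or acid.size == 0:
        raise ValueError("both event sets must be nonempty")
    hi_n = float(native.max())
    hi_a = float(acid.max())
    m_native = fit_mixture(native, k=3, window=(complex_floor_kda, hi_n), seed=seed)
    m_acid = fit_mixture(acid, k=2, window=(complex_floor_kda, hi_a), seed=seed)

    def pick(model: MixtureModel) -> np.ndarray:
        if weight_source == "event_counts" and not np.any(np.isnan(model.event_count_weights)):
            return np.asarray(model.event_count_weights)
        return model.weights

    wn = pick(m_native)
    wa = pick(m_acid)
    f7 = float(wa[-1] / wa.sum())
    # Expected native population centers from the acidified complexes:
    # light = α6β1, heavy = α7β1+ProS, middle = the overlapped pair.
    m6_hat, m7_hat = m_acid.means
    centers = np.array(
        [m6_hat, 0.5 * (m7_hat + m6_hat + m_pros_kda), m7_hat + m_pros_kda]
    )
    acc = np.zeros(3)
    for mean, w in zip(m_native.means, wn):
        acc[int(np.argmin(np.abs(centers - mean)))] += w
    a3, a2, a1 = (acc / acc.sum()).tolist()
    return resolve_overlap(a1, a2, a3, f7)


@dataclass
class ShiftReport:
    """Native→acidified component pairing with dissociation flags."""

    pairs: list[tuple[float, float, float]]  # (native mean, acid mean, delta kDa)
    flagged_dissociation: list[tuple[float, float, float]]
    unmatched_native: list[float]
    unmatched_acidified: list[float]


def detect_shift(
    native: MixtureModel,
    acidified: MixtureModel,
    m_pros_kda: float = 79.8,
    tol_kda: float = 15.0,
) -> ShiftReport:
    """Pair native and acidified components (greedy, heaviest native
    first, nearest acidified mean; ties toward smaller Δ) and flag pairs
    whose downward shift matches the ProS mass within tolerance."""
    nat = sorted(native.means.tolist(), reverse=True)
    acid = sorted(acidified.means.tolist(), reverse=True)
    available = list(acid)
    pairs, flagged = [], []
    for nm in nat:
        if not available:
            break
        am = min(available, key=lambda a: (abs(nm - a), nm - a))
        available.remove(am)
        delta = nm - am
        pairs.append((nm, am, delta))
        if m_pros_kda - tol_kda <= delta <= m_pros_kda + tol_kda:
            flagged.append((nm, am, delta))
    matched_nat = {p[0] for p in pairs}
    return ShiftReport(
        pairs=pairs,
        flagged_dissociation=flagged,
        unmatched_native=[m for m in nat if m not in matched_nat],
        unmatched_acidified=available,
    )
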