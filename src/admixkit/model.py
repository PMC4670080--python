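"""The demographic core: pulse-migration tract-length models.

Three nested hypotheses about an admixed population's history are
supported, each a :class:`MigrationSchedule` builder with the migration
magnitudes pinned in closed form by the observed genome-wide ancestry
proportions, so only event *times* (and, for the pulse models, the extra
pulse's magnitude) are free:

``base``
    founding admixture between two source populations (EUR/NAT) at ``t0``
    generations before present, followed by a single pulse of AFR
    migration at ``t_afr``; free parameters ``(t0, t_afr)``.
``base+eur_pulse`` / ``base+afr_pulse``
    the base model plus one later pulse of EUR (resp. AFR) migration with
    free ``(t_pulse, m_pulse)``.

The likelihood treats each tract-length bin (and each whole-chromosome
category) as an independent Poisson cell — a composite likelihood, since
tracts on one haplotype are correlated.  Expected counts come from a
Markov model of ancestry along the genome whose correctness contract is
agreement with the forward pedigree simulator (:mod:`admixkit.simulate`)
within Monte-Carlo error.

The Markov model: at a locus, the sampled lineage's state is ``(t, p)`` —
its most recent migrant ancestor entered ``t`` generations ago from source
``p``.  Moving along the genome, crossovers on the ``t - 1`` meioses of
the lineage occur at rate ``t - 1`` per Morgan; a crossover at meiosis
depth ``d < t - 1`` re-draws the lineage above generation ``d + 1`` from
the migrants available at generations ``>= d + 2``, while a crossover at
the migrant's own meiosis leaves the ancestry unchanged.  Tract lengths of
an ancestry are phase-type sojourn times in that ancestry's state class,
with explicit handling of chromosome-end truncation and whole-chromosome
tracts.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln
from scipy.stats import qmc

from .genome import ChromosomeSet
from .schedule import MigrationSchedule, ScheduleValidationError
from .spectrum import ExpectedSpectrum, TractLengthSpectrum

__all__ = [
    "InfeasibleParametersError",
    "FitFailureError",
    "MODEL_PARAMS",
    "build_migration_schedule",
    "schedule_proportions",
    "expected_tract_spectrum",
    "poisson_loglik",
    "TractModel",
    "TractModelResults",
    "fit_model",
]

MODEL_PARAMS: dict[str, tuple[str, ...]] = {
    "base": ("t0", "t_afr"),
    "base+eur_pulse": ("t0", "t_afr", "t_pulse", "m_pulse"),
    "base+afr_pulse": ("t0", "t_afr", "t_pulse", "m_pulse"),
}

TIME_BOUNDS = (2.0, 25.0)
MAG_BOUNDS = (0.001, 0.999)

_INT_EPS = 1e-9


class InfeasibleParametersError(ValueError):
    """No migration schedule with fractions in [0, 1] matches the requested
    parameters and observed proportions."""


class FitFailureError(RuntimeError):
    """All optimizer starts were infeasible or failed."""


# ----------------------------------------------------------------------
# Schedule construction: continuous times on the integer generation grid
# ----------------------------------------------------------------------
def _split_event(t: float) -> list[tuple[int, float]]:
    """Map a continuous event time to the integer grid: weight ``1 - phi``
    at ``floor(t)`` and ``phi`` at ``ceil(t)`` for fractional part ``phi``."""
    f = math.floor(t + _INT_EPS)
    phi = t - f
    if phi <= _INT_EPS:
        return [(f, 1.0)]
    return [(f, 1.0 - phi), (f + 1, phi)]


def _eval_proportions(events: list[tuple[int, int, float]], n_pops: int, T0: int) -> np.ndarray:
    """Final ancestry fractions implied by a discrete event list
    ``(generation, pop_index, magnitude)`` (same-generation events summed)."""
    rates = np.zeros((T0 + 1, n_pops))
    for g, p, m in events:
        rates[g, p] += m
    M = rates.sum(axis=1)
    a = np.zeros(n_pops)
    surv = 1.0
    for t in range(2, T0 + 1):
        a += rates[t] * surv
        surv *= 1.0 - M[t]
    return a


def build_migration_schedule(
    model_id: str,
    params: dict[str, float],
    proportions: dict[str, float],
    labels: tuple[str, str, str] = ("EUR", "NAT", "AFR"),
) -> MigrationSchedule:
    """Build the discrete migration schedule for a model parameterisation.

    Magnitudes not listed as free parameters (the founding EUR/NAT split
    and the base AFR pulse) are solved in closed form so that the
    schedule-implied final proportions equal ``proportions`` exactly.
    Continuous event times are split across the two adjacent integer
    generations in proportion to the fractional part; a fractional
    founding time ``t0`` becomes a full founding at ``ceil(t0)`` plus a
    replacement pulse of magnitude ``1 - frac(t0)`` with founding
    composition at ``floor(t0)``.

    Raises :class:`InfeasibleParametersError` when no schedule with all
    fractions in [0, 1] exists.
    """
    if model_id not in MODEL_PARAMS:
        raise ValueError(f"unknown model {model_id!r}; expected one of {sorted(MODEL_PARAMS)}")
    eur, nat, afr = labels
    pE, pN, pA = (float(proportions[k]) for k in labels)
    if abs(pE + pN + pA - 1.0) > 1e-8:
        raise ValueError("observed proportions must sum to 1")
    t0 = float(params["t0"])
    t_afr = float(params["t_afr"])
    if not (1.0 < t_afr < t0):
        raise InfeasibleParametersError(f"need 1 < t_afr < t0, got t_afr={t_afr}, t0={t0}")

    G0 = math.ceil(t0 - _INT_EPS)
    phi0 = t0 - math.floor(t0 + _INT_EPS)
    afr_split = _split_event(t_afr)

    extra: list[tuple[int, float]] = []
    extra_pop: int | None = None
    if model_id in ("base+eur_pulse", "base+afr_pulse"):
        t_pulse = float(params["t_pulse"])
        m_pulse = float(params["m_pulse"])
        if not (1.0 < t_pulse < t0):
            raise InfeasibleParametersError(
                f"need 1 < t_pulse < t0, got t_pulse={t_pulse}, t0={t0}"
            )
        if not 0.0 <= m_pulse <= 1.0:
            raise InfeasibleParametersError("m_pulse outside [0, 1]")
        extra = [(g, w * m_pulse) for g, w in _split_event(t_pulse)]
        extra_pop = 0 if model_id == "base+eur_pulse" else 2

    def assemble(mA: float, fE: float) -> list[tuple[int, int, float]]:
        events: list[tuple[int, int, float]] = [(G0, 0, fE), (G0, 1, 1.0 - fE)]
        if phi0 > _INT_EPS:
            events += [(G0 - 1, 0, (1.0 - phi0) * fE), (G0 - 1, 1, (1.0 - phi0) * (1.0 - fE))]
        events += [(g, 2, w * mA) for g, w in afr_split]
        if extra_pop is not None:
            events += [(g, extra_pop, w) for g, w in extra]
        return events

    for g, _ in afr_split + [(g, w) for g, w in extra]:
        if g < 2:
            raise InfeasibleParametersError(f"event at generation {g} < 2")
        if g >= G0:
            raise InfeasibleParametersError(
                f"pulse generation {g} not more recent than founding at {G0}"
            )

    # AFR magnitude: a_AFR(mA) is quadratic in mA (the two split halves of
    # the pulse discount each other); fit the quadratic exactly and solve.
    h = [_eval_proportions(assemble(m, 0.5), 3, G0)[2] for m in (0.0, 0.5, 1.0)]
    qa = 2.0 * h[2] + 2.0 * h[0] - 4.0 * h[1]
    qb = h[2] - h[0] - qa
    qc = h[0] - pA
    if abs(qa) < 1e-12:
        if abs(qb) < 1e-12:
            mA = 0.0 if abs(qc) < 1e-10 else math.nan
        else:
            mA = -qc / qb
    else:
        disc = qb * qb - 4.0 * qa * qc
        if disc < 0:
            mA = math.nan
        else:
            roots = sorted(((-qb + s * math.sqrt(disc)) / (2.0 * qa) for s in (1.0, -1.0)))
            mA = next((r for r in roots if -1e-10 <= r <= 1.0 + 1e-10), math.nan)
    if not (math.isfinite(mA) and -1e-10 <= mA <= 1.0 + 1e-10):
        raise InfeasibleParametersError(
            f"no AFR pulse magnitude in [0, 1] reaches proportion {pA}"
        )
    mA = min(max(mA, 0.0), 1.0)

    # Founding split: a_NAT(fE) is linear in fE.
    g0 = _eval_proportions(assemble(mA, 0.0), 3, G0)[1]
    g1 = _eval_proportions(assemble(mA, 1.0), 3, G0)[1]
    if abs(g1 - g0) < 1e-12:
        raise InfeasibleParametersError("founding fraction cannot be pinned (degenerate)")
    fE = (pN - g0) / (g1 - g0)
    if not -1e-10 <= fE <= 1.0 + 1e-10:
        raise InfeasibleParametersError(
            f"founding EUR fraction {fE:.4f} outside [0, 1]"
        )
    fE = min(max(fE, 0.0), 1.0)

    events = assemble(mA, fE)
    rates = np.zeros((G0 + 1, 3))
    for g, p, m in events:
        rates[g, p] += m
    if np.any(rates.sum(axis=1)[2:-1] > 1.0 + 1e-9):
        raise InfeasibleParametersError("per-generation replacement exceeds 1")
    try:
        schedule = MigrationSchedule((eur, nat, afr), rates)
    except ScheduleValidationError as exc:
        raise InfeasibleParametersError(str(exc)) from exc
    got = schedule.proportions()
    if abs(got[eur] - pE) > 1e-8:
        raise InfeasibleParametersError(
            f"solved schedule misses EUR proportion: {got[eur]:.6f} vs {pE:.6f}"
        )
    return schedule


def schedule_proportions(schedule: MigrationSchedule) -> dict[str, float]:
    """Final genome fraction per source population implied by a schedule."""
    return schedule.proportions()


# ----------------------------------------------------------------------
# The ancestry process along the genome
# ----------------------------------------------------------------------
def _gamete_markov_chain(schedule: MigrationSchedule, g0: int):
    """Markov closure of the gamete-of-a-generation-``g0``-individual
    process: states ``(u, p)`` (migrant ancestor at generation ``u >= g0``
    from source ``p``), stationary initial distribution, and the per-Morgan
    generator.  A crossover in the meiosis of the lineage's generation-``d``
    individual (``g0 <= d < u``) re-draws the lineage above from the
    migrants available at generations ``>= d + 1``; the migrant's own
    meiosis never changes ancestry.  Returns ``(anc, pi, Q)``."""
    T0 = schedule.founding_time
    rates = schedule.rates
    M = schedule.total_inflow()
    states = [
        (u, p) for u in range(g0, T0 + 1) for p in range(schedule.n_pops) if rates[u, p] > 0
    ]
    S = len(states)
    # fresh[g]: state distribution of a gamete from a generation-g individual
    fresh = np.zeros((T0 + 2, S))
    for g in range(g0, T0 + 1):
        for j, (u, p) in enumerate(states):
            if u >= g:
                prod = 1.0
                for s in range(g, u):
                    prod *= 1.0 - M[s]
                fresh[g, j] = rates[u, p] * prod
    pi = fresh[g0].copy()
    Q = np.zeros((S, S))
    for i, (u, _p) in enumerate(states):
        row = np.zeros(S)
        for g in range(g0 + 1, u + 1):
            row += fresh[g]
        row[i] = 0.0
        Q[i] = row
        Q[i, i] = -row.sum()
    anc = np.array([p for _u, p in states], dtype=np.int64)
    return anc, pi, Q


def _pair_chain(anc, pi, Q):
    """The gamete of a non-migrant individual toggles, at crossover rate 1
    per Morgan, between the individual's two haplotypes — themselves
    independent gametes of the previous generation.  Given that inner
    gamete process, build the (active, passive) pair chain: both
    coordinates evolve independently under ``Q`` while the swap exchanges
    them; the visible ancestry is the active coordinate's."""
    S = anc.size
    n = S * S
    anc2 = np.repeat(anc, S)
    pi2 = np.kron(pi, pi)
    eye = np.eye(S)
    Q2 = np.kron(Q, eye) + np.kron(eye, Q)
    # swap (i, j) -> (j, i) at rate 1
    idx = np.arange(n)
    i, j = divmod(idx, S)
    swapped = j * S + i
    off = idx != swapped
    Q2[idx[off], swapped[off]] += 1.0
    Q2[idx[off], idx[off]] -= 1.0
    return anc2, pi2, Q2


def _mixture_with_migrants(schedule: MigrationSchedule, g: int, anc, pi, Q):
    """Prepend absorbing pure-ancestry states for the case that the
    generation-``g`` individual is itself a migrant (probability ``M(g)``)."""
    rates = schedule.rates
    pure = [p for p in range(schedule.n_pops) if rates[g, p] > 0]
    if not pure:
        return anc, pi, Q
    k = len(pure)
    S = anc.size
    anc_new = np.concatenate([np.array(pure, dtype=np.int64), anc])
    Mg = rates[g].sum()
    pi_new = np.concatenate([rates[g][pure], (1.0 - Mg) * pi])
    Q_new = np.zeros((k + S, k + S))
    Q_new[k:, k:] = Q
    return anc_new, pi_new, Q_new


def ancestry_chain(schedule: MigrationSchedule, depth: int = 2):
    """Markov chain of the local-ancestry process along a sampled
    haplotype, per Morgan: ``(anc, pi, Q)`` with ``anc`` the ancestry
    index of each state and ``pi`` the (stationary) state distribution at
    any genomic position.

    ``depth`` controls how many of the top meioses are represented exactly
    by the pair-of-gametes construction before the Markov closure takes
    over: a sampled haplotype is the gamete of its generation-2 parent,
    which toggles between two independent generation-3 gametes, and so on.
    ``depth=0`` is the plain renewal-type Markov model; each extra level
    captures more of the long-range dependence created by crossovers
    toggling between the same two parental haplotypes (which the pure
    Markov model understates, visibly so for whole-chromosome tracts).
    The construction is exact when ``2 + depth >= T0``."""
    T0 = schedule.founding_time
    g0 = min(2 + max(depth, 0), T0)
    anc, pi, Q = _gamete_markov_chain(schedule, g0)
    for g in range(g0 - 1, 1, -1):
        anc, pi, Q = _pair_chain(anc, pi, Q)
        anc, pi, Q = _mixture_with_migrants(schedule, g, anc, pi, Q)
    return anc, pi, Q


def markov_chain(schedule: MigrationSchedule):
    """Plain renewal Markov chain (``depth=0``) with explicit ``(t, p)``
    state labels; kept for diagnostics and tests."""
    anc, pi, Q = ancestry_chain(schedule, depth=0)
    T0 = schedule.founding_time
    states = [
        (t, p)
        for t in range(2, T0 + 1)
        for p in range(schedule.n_pops)
        if schedule.rates[t, p] > 0
    ]
    return states, pi, Q


def _ik_scalars(lam: np.ndarray, xs: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """``e^{lam x}``, ``int_0^x e^{lam s} ds``, ``int s e``, ``int s^2 e``
    for each (eigenvalue, x) pair; series expansion near ``lam x = 0`` for
    numerical stability.  Shapes ``(n_lam, n_x)``, complex."""
    lam = lam[:, None]
    x = xs[None, :]
    z = lam * x
    small = np.abs(z) < 0.25
    zs = np.where(small, z, 0.0)
    ls = np.where(np.abs(lam) > 0, lam, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        E = np.exp(z)
        I0 = (E - 1.0) / ls
        I1 = x * E / ls - (E - 1.0) / ls**2
        I2 = x * x * E / ls - 2.0 * x * E / ls**2 + 2.0 * (E - 1.0) / ls**3
    s0 = np.zeros_like(z)
    s1 = np.zeros_like(z)
    s2 = np.zeros_like(z)
    term = np.ones_like(z)
    fact = 1.0
    for k in range(14):
        if k > 0:
            term = term * zs
            fact *= k
        s0 = s0 + term / (fact * (k + 1))
        s1 = s1 + term / (fact * (k + 2))
        s2 = s2 + term / (fact * (k + 3))
    I0 = np.where(small, x * s0, I0)
    I1 = np.where(small, x * x * s1, I1)
    I2 = np.where(small, x**3 * s2, I2)
    return E, I0, I1, I2


def _class_pieces(A: np.ndarray, alpha0: np.ndarray, beta: np.ndarray, xs: np.ndarray, L: float):
    """Cumulative tract-count and length-mass functions for one ancestry
    class on a chromosome of length ``L`` Morgans.

    Returns ``(cum_counts, cum_mass, whole, total_mass)`` where the
    cumulative arrays are evaluated at ``xs`` followed by ``L`` (length
    ``xs.size + 1``), ``whole`` is the expected whole-chromosome tract
    count and ``total_mass`` the expected total tract length (Morgans)
    including the whole-chromosome mass — all per haplotype.  Counts sum
    three tract kinds: interior (both ends from ancestry switches),
    right-truncated at the chromosome end, and left-truncated at position
    0; a tract spanning the whole chromosome is only in ``whole``."""
    S = A.shape[0]
    ones = np.ones(S)
    r = -A @ ones  # exit rate to other ancestry classes
    lam, V = np.linalg.eig(A)
    try:
        Vi = np.linalg.inv(V)
    except np.linalg.LinAlgError:  # defective; perturb infinitesimally
        Vi = np.linalg.pinv(V)
    aV = alpha0 @ V
    bV = beta @ V
    Vr = Vi @ r
    V1 = Vi @ ones
    xs_all = np.append(xs, L)
    E, I0, I1, I2 = _ik_scalars(lam, xs_all)

    def proj(left, mats, right):
        return np.real(np.einsum("i,ix,i->x", left, mats, right))

    c_int = L * proj(bV, I0, Vr) - proj(bV, I1, Vr)
    c_rc = proj(bV, I0, V1)
    c_ls = proj(aV, I0, Vr)
    m_int = L * proj(bV, I1, Vr) - proj(bV, I2, Vr)
    m_rc = proj(bV, I1, V1)
    m_ls = proj(aV, I1, Vr)
    cum_counts = c_int + c_rc + c_ls
    cum_mass = m_int + m_rc + m_ls
    whole = float(np.real(np.einsum("i,i,i->", aV, E[:, -1], V1)))
    total_mass = float(cum_mass[-1]) + whole * L
    return cum_counts, cum_mass, whole, total_mass


DEFAULT_CHAIN_DEPTH = 0


def expected_tract_spectrum(
    schedule: MigrationSchedule,
    chroms: ChromosomeSet,
    edges: np.ndarray,
    n_haplotypes: int,
    depth: int | None = None,
) -> ExpectedSpectrum:
    """Expected tract-length spectrum under the analytic ancestry model
    (:func:`ancestry_chain`; tract lengths are phase-type sojourns in an
    ancestry's state class).

    Bins follow the :class:`TractLengthSpectrum` convention (left edges,
    last bin open-ended, whole-chromosome tracts in their own per-
    chromosome category).  End-truncated tracts are included in the bins
    with their truncated lengths, mirroring what tract extraction from
    real or simulated haplotypes produces.
    """
    edges = np.asarray(edges, dtype=float)
    if edges.size < 1:
        raise ValueError("at least one bin edge is required")
    if depth is None:
        depth = DEFAULT_CHAIN_DEPTH
    anc, pi, Q = ancestry_chain(schedule, depth=depth)
    pops = schedule.populations
    A_n = len(pops)
    mu = np.zeros((A_n, edges.size))
    full_mu = np.zeros((A_n, len(chroms)))
    lmass = np.zeros(A_n)

    lengths_M = np.asarray(chroms.lengths_cM) / 100.0
    edges_M = edges / 100.0
    for p in range(A_n):
        idx = np.flatnonzero(anc == p)
        if idx.size == 0:
            continue
        other = np.flatnonzero(anc != p)
        A = Q[np.ix_(idx, idx)]
        alpha0 = pi[idx]
        beta = pi[other] @ Q[np.ix_(other, idx)] if other.size else np.zeros(idx.size)
        for L in np.unique(lengths_M):
            which = np.flatnonzero(np.isclose(lengths_M, L))
            xs = np.clip(edges_M, 0.0, L)
            cum_c, _, whole, total = _class_pieces(A, alpha0, beta, xs, L)
            # bin b spans [edges[b], edges[b+1]); the last bin is open and
            # effectively runs to L (cum_c[-1] is the cumulative at L)
            binned = np.diff(cum_c)
            n_rep = len(which) * n_haplotypes
            mu[p] += n_rep * binned
            full_mu[p, which] += n_haplotypes * whole
            lmass[p] += n_rep * total * 100.0
    return ExpectedSpectrum(
        edges=edges,
        ancestries=pops,
        mu=mu,
        full_mu=full_mu,
        length_mass=lmass,
        n_haplotypes=n_haplotypes,
        chromosomes=chroms,
        proportions=schedule.proportions(),
    )


# ----------------------------------------------------------------------
def poisson_loglik(observed: TractLengthSpectrum, expected: ExpectedSpectrum) -> float:
    """Poisson composite log-likelihood over all bins and whole-chromosome
    categories: ``sum o ln mu - mu - ln o!`` with ``0 ln 0 = 0``; a cell
    with ``mu = 0`` and ``o > 0`` yields ``-inf``."""
    if observed.edges.shape != expected.edges.shape or np.any(observed.edges != expected.edges):
        raise ValueError("observed and expected spectra use different bins")
    if observed.ancestries != expected.ancestries:
        raise ValueError("observed and expected spectra use different ancestries")
    o = observed.cells().astype(float)
    m = expected.cells()
    ll = 0.0
    pos = m > 0
    ll += float(np.sum(o[pos] * np.log(m[pos]) - m[pos] - gammaln(o[pos] + 1.0)))
    if np.any(o[~pos] > 0):
        return -math.inf
    return ll


# ----------------------------------------------------------------------
# Model / Results
# ----------------------------------------------------------------------
class TractModel:
    """Pulse-migration model for an observed tract-length spectrum.

    Parameters
    ----------
    spectrum
        Observed :class:`TractLengthSpectrum`.
    model
        ``"base"``, ``"base+eur_pulse"`` or ``"base+afr_pulse"``.
    proportions
        Observed genome-wide ancestry fractions (from
        :func:`admixkit.ancestry.ancestry_proportions` over the same
        cohort); these pin the migration magnitudes.
    labels
        The (EUR-role, NAT-role, AFR-role) ancestry labels.
    """

    def __init__(
        self,
        spectrum: TractLengthSpectrum,
        model: str = "base",
        proportions: dict[str, float] | None = None,
        labels: tuple[str, str, str] = ("EUR", "NAT", "AFR"),
        depth: int | None = None,
    ) -> None:
        if model not in MODEL_PARAMS:
            raise ValueError(f"unknown model {model!r}")
        if spectrum.total_tracts == 0:
            raise FitFailureError("empty tract spectrum")
        if proportions is None:
            raise ValueError("observed ancestry proportions are required")
        self.spectrum = spectrum
        self.model = model
        self.labels = labels
        self.proportions = {k: float(proportions[k]) for k in labels}
        self.param_names = MODEL_PARAMS[model]
        self.chromosomes = spectrum.chromosomes
        self.depth = DEFAULT_CHAIN_DEPTH if depth is None else int(depth)
        self._fast = self._prepare_fast() if self.depth == 0 else None

    def _prepare_fast(self):
        """Precompute the observed-spectrum arrays consumed by the numba
        likelihood (``admixkit._fast.loglike0``)."""
        s = self.spectrum
        extra = set(s.ancestries) - set(self.labels)
        if any(s.counts[s.ancestries.index(a)].sum() or s.full_counts[s.ancestries.index(a)].sum()
               for a in extra):
            return None  # spectrum carries ancestries the model cannot emit
        lengths_M = np.asarray(s.chromosomes.lengths_cM) / 100.0
        uniqL, inv = np.unique(lengths_M, return_inverse=True)
        nrepL = np.bincount(inv).astype(float)
        obs_counts = np.zeros((3, s.edges.size))
        obs_full_sum = np.zeros((3, uniqL.size))
        obs_full_lgam = np.zeros((3, uniqL.size))
        for i, lab in enumerate(self.labels):
            if lab not in s.ancestries:
                continue
            row = s.ancestries.index(lab)
            obs_counts[i] = s.counts[row]
            for li in range(uniqL.size):
                cc = s.full_counts[row][inv == li].astype(float)
                obs_full_sum[i, li] = cc.sum()
                obs_full_lgam[i, li] = float(gammaln(cc + 1.0).sum())
        obs_bin_lgam = float(gammaln(obs_counts + 1.0).sum())
        props = np.array([self.proportions[lab] for lab in self.labels])
        code = {"base": 0, "base+eur_pulse": 1, "base+afr_pulse": 2}[self.model]
        return {
            "code": code,
            "props": props,
            "edgesM": s.edges / 100.0,
            "uniqL": uniqL,
            "nrepL": nrepL,
            "obs_counts": obs_counts,
            "obs_full_sum": obs_full_sum,
            "obs_full_lgam": obs_full_lgam,
            "obs_bin_lgam": obs_bin_lgam,
        }

    # ------------------------------------------------------------------
    def expected(self, params: np.ndarray | dict) -> ExpectedSpectrum:
        if isinstance(params, dict):
            pdict = params
        else:
            pdict = dict(zip(self.param_names, np.asarray(params, dtype=float)))
        schedule = build_migration_schedule(self.model, pdict, self.proportions, self.labels)
        return expected_tract_spectrum(
            schedule,
            self.chromosomes,
            self.spectrum.edges,
            self.spectrum.n_haplotypes,
            depth=self.depth,
        )

    def loglike(self, params: np.ndarray | dict) -> float:
        if isinstance(params, dict):
            params = np.array([params[k] for k in self.param_names], dtype=float)
        else:
            params = np.asarray(params, dtype=float)
        if self._fast is not None:
            from ._fast import loglike0

            f = self._fast
            tp, mp = (params[2], params[3]) if params.size == 4 else (0.0, 0.0)
            ll = loglike0(
                f["code"], params[0], params[1], tp, mp, f["props"], f["edgesM"],
                f["uniqL"], f["nrepL"], float(self.spectrum.n_haplotypes),
                f["obs_counts"], f["obs_full_sum"], f["obs_full_lgam"], f["obs_bin_lgam"],
            )
            return -math.inf if ll <= -1e17 else float(ll)
        try:
            return poisson_loglik(self.spectrum, self.expected(params))
        except InfeasibleParametersError:
            return -math.inf

    # ------------------------------------------------------------------
    def _penalised_negll(self, x: np.ndarray) -> float:
        pen = 0.0
        for i, name in enumerate(self.param_names):
            lo, hi = MAG_BOUNDS if name.startswith("m_") else TIME_BOUNDS
            if x[i] < lo:
                pen += lo - x[i]
            elif x[i] > hi:
                pen += x[i] - hi
        t0 = x[0]
        for i, name in enumerate(self.param_names):
            if name.startswith("t_") and x[i] >= t0 - 1e-6:
                pen += x[i] - t0 + 1.0
        if pen > 0:
            return 1e12 * (1.0 + pen)
        ll = self.loglike(x)
        if not math.isfinite(ll):
            return 1e10
        return -ll

    def _draw_starts(self, n: int, seed) -> np.ndarray:
        sampler = qmc.LatinHypercube(d=len(self.param_names), seed=seed)
        u = sampler.random(n)
        starts = np.empty_like(u)
        t0 = TIME_BOUNDS[0] + 2.0 + u[:, 0] * (TIME_BOUNDS[1] - TIME_BOUNDS[0] - 4.0)
        starts[:, 0] = t0
        for i, name in enumerate(self.param_names[1:], start=1):
            if name.startswith("m_"):
                starts[:, i] = 0.01 + u[:, i] * 0.5
            else:
                starts[:, i] = TIME_BOUNDS[0] + u[:, i] * (t0 - TIME_BOUNDS[0] - 0.5)
        return starts

    def fit(
        self,
        n_starts: int = 10,
        seed: int | None = 0,
        warm_starts: list[np.ndarray] | None = None,
        fatol: float = 1e-6,
        xatol: float = 1e-4,
        maxiter: int | None = None,
    ) -> "TractModelResults":
        """Maximise the Poisson composite likelihood by multi-start
        Nelder-Mead over the model's free parameters."""
        from scipy.optimize import minimize

        starts = list(self._draw_starts(n_starts, seed)) if n_starts > 0 else []
        for w in warm_starts or []:
            starts.insert(0, np.asarray(w, dtype=float))
        if not starts:
            raise FitFailureError("no starts supplied")
        best = None
        n_ok = 0
        for x0 in starts:
            if self._penalised_negll(np.asarray(x0)) >= 1e10:
                continue
            res = minimize(
                self._penalised_negll,
                np.asarray(x0, dtype=float),
                method="Nelder-Mead",
                options={
                    "fatol": fatol,
                    "xatol": xatol,
                    "maxiter": maxiter or 400 * len(self.param_names),
                },
            )
            if res.fun >= 1e10:
                continue
            n_ok += 1
            if best is None or res.fun < best.fun:
                best = res
        if best is None:
            raise FitFailureError(
                f"all {len(starts)} optimizer starts infeasible for model {self.model!r} "
                f"with proportions {self.proportions}"
            )
        params = dict(zip(self.param_names, best.x.astype(float)))
        return TractModelResults(
            model=self,
            params=params,
            llf=-float(best.fun),
            converged=bool(best.success),
            n_starts=len(starts),
            n_feasible_starts=n_ok,
        )


@dataclass
class TractModelResults:
    """Fitted pulse-migration model: point estimates, composite
    log-likelihood and the expected spectrum at the optimum."""

    model: TractModel
    params: dict[str, float]
    llf: float
    converged: bool
    n_starts: int
    n_feasible_starts: int
    _expected: ExpectedSpectrum | None = field(default=None, repr=False)
    _bse: dict[str, float] | None = field(default=None, repr=False)

    @property
    def expected_spectrum(self) -> ExpectedSpectrum:
        if self._expected is None:
            self._expected = self.model.expected(self.params)
        return self._expected

    @property
    def x(self) -> np.ndarray:
        return np.array([self.params[k] for k in self.model.param_names])

    def bic(self) -> float:
        """Bayesian information criterion with the observed tract count as
        the sample size (a reporting convenience; model choice should use
        the simulation-calibrated test in :mod:`admixkit.selection`)."""
        k = len(self.params)
        n = max(self.model.spectrum.total_tracts, 2)
        return k * math.log(n) - 2.0 * self.llf

    def bse(self) -> dict[str, float]:
        """Approximate standard errors from the inverse numerical Hessian
        of the composite log-likelihood.  Composite-likelihood curvature
        understates tract-to-tract dependence, so these are optimistic and
        are reported for orientation only."""
        if self._bse is None:
            x = self.x
            k = x.size
            h = np.maximum(1e-3, 1e-3 * np.abs(x))
            H = np.zeros((k, k))
            f0 = self.model.loglike(x)
            for i in range(k):
                for j in range(i, k):
                    ei = np.zeros(k)
                    ej = np.zeros(k)
                    ei[i] = h[i]
                    ej[j] = h[j]
                    fpp = self.model.loglike(x + ei + ej)
                    fpm = self.model.loglike(x + ei - ej)
                    fmp = self.model.loglike(x - ei + ej)
                    fmm = self.model.loglike(x - ei - ej)
                    vals = [fpp, fpm, fmp, fmm]
                    if all(math.isfinite(v) for v in vals):
                        H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
                    else:
                        H[i, j] = H[j, i] = math.nan
            try:
                cov = np.linalg.inv(-H)
                se = np.sqrt(np.clip(np.diag(cov), 0, None))
            except np.linalg.LinAlgError:
                se = np.full(k, math.nan)
            self._bse = dict(zip(self.model.param_names, se.tolist()))
        return self._bse

    def summary(self) -> str:
        lines = [
            "Tract-length pulse-migration model",
            "=" * 46,
            f"model:            {self.model.model}",
            f"log-likelihood:   {self.llf:.3f}   (Poisson composite)",
            f"BIC:              {self.bic():.3f}",
            f"converged:        {self.converged}  (starts: {self.n_feasible_starts}/{self.n_starts} feasible)",
            f"haplotypes:       {self.model.spectrum.n_haplotypes}",
            f"tracts:           {self.model.spectrum.total_tracts}",
            "-" * 46,
            f"{'parameter':<12}{'estimate':>12}{'approx se':>12}",
        ]
        bse = self.bse()
        for name in self.model.param_names:
            lines.append(f"{name:<12}{self.params[name]:>12.4f}{bse[name]:>12.4f}")
        lines.append("-" * 46)
        lines.append("pinned proportions: " + ", ".join(f"{k}={v:.4f}" for k, v in self.model.proportions.items()))
        return "\n".join(lines)

    def to_json(self, path=None) -> str:
        payload = {
            "model": self.model.model,
            "params": self.params,
            "llf": self.llf,
            "bic": self.bic(),
            "converged": self.converged,
            "n_starts": self.n_starts,
            "proportions": self.model.proportions,
        }
        s = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s

    def plot_spectrum(self, ax=None, log=True):
        """Observed-vs-expected tract-length decay curves per ancestry."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        exp = self.expected_spectrum
        obs = self.model.spectrum
        centers = exp.edges + 0.5 * np.median(np.diff(exp.edges)) if exp.edges.size > 1 else exp.edges
        for a, anc in enumerate(exp.ancestries):
            ax.plot(centers, exp.mu[a], "-", label=f"{anc} expected")
            ax.plot(centers, obs.counts[a], ".", label=f"{anc} observed")
        if log:
            ax.set_yscale("log")
        ax.set_xlabel("tract length (cM)")
        ax.set_ylabel("tract count")
        ax.legend(fontsize=7)
        return ax


def fit_model(
    observed: TractLengthSpectrum,
    model_id: str,
    proportions: dict[str, float],
    chroms: ChromosomeSet | None = None,
    n_starts: int = 10,
    seed: int | None = 0,
    labels: tuple[str, str, str] = ("EUR", "NAT", "AFR"),
    **kwargs,
) -> TractModelResults:
    """Functional wrapper: build a :class:`TractModel` and fit it."""
    del chroms  # carried by the spectrum
    return TractModel(observed, model_id, proportions, labels).fit(
        n_starts=n_starts, seed=seed, **kwargs
    )
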