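"""Allometric trophic network (ATN) dynamics with nutrients.

Bioenergetic consumer-resource model in the Yodzis-Innes tradition: all
biological rates (metabolism, encounter, handling, interference, basal
growth) scale with species body mass and with temperature through
Boltzmann-Arrhenius factors. Basal species compete for two shared
nutrients; consumers feed through a saturating functional response whose
exponent ``1 + q`` interpolates between type II and type III. Foraging
effort of each consumer across its prey is either split uniformly
(static policy) or driven by an empirically parameterized skew-normal
preference distribution over log10 prey body mass (flexible policy).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "ATNParameters",
    "Community",
    "ForagingPolicy",
    "SimulationResult",
    "arrhenius",
    "ricker_niche",
    "metabolic_rate",
    "functional_response",
    "foraging_weights",
    "derivatives",
    "simulate",
]

#: Boltzmann constant in eV per Kelvin.
BOLTZMANN_EV = 8.6173e-5


@dataclass
class ATNParameters:
    """Rate constants, activation energies and solver-facing constants.

    Defaults are the "unscaled ATN with nutrients" parameterization:
    assimilation efficiencies ``e_P`` (plant prey) and ``e_A`` (animal
    prey), metabolic normalization ``x0`` with allometric exponent -0.25,
    activation energies (eV) for metabolism ``E_x``, encounter ``E_p``,
    handling ``E_h``, interference ``E_c`` and basal growth ``E_r``,
    reference temperature ``T0`` (K), optimal consumer-resource mass
    ratio ``R_opt``, Ricker exponent ``gamma_R``, link threshold on the
    feeding niche, handling normalization ``h0``, hill parameter ``q``,
    nutrient turnover ``D``, supply ``S_l`` and plant nutrient contents
    ``v``. The Arrhenius convention is ``exp(E (T0 - T) / (k T0 T))``:
    a *negative* activation energy means the rate increases with
    warming.
    """

    e_P: float = 0.545
    e_A: float = 0.906
    x0: float = 0.314
    E_x: float = -0.69
    E_p: float = -0.38
    E_h: float = 0.26
    E_c: float = -0.65
    E_r: float = 0.25
    T0: float = 293.15
    T: float = 293.15
    p0: float = 1.0
    beta_consumer: tuple[float, float] = (0.47, 0.04)
    beta_resource: tuple[float, float] = (0.15, 0.03)
    R_opt: float = 71.68
    gamma_R: float = 2.0
    niche_threshold: float = 0.01
    h0: float = 0.4
    eta_consumer: tuple[float, float] = (-0.48, 0.03)
    eta_resource: tuple[float, float] = (-0.66, 0.02)
    c0: tuple[float, float] = (0.8, 0.2)
    q: float = 1.2
    D: float = 0.25
    S: tuple[float, float] = (5.0, 5.0)
    v: tuple[float, float] = (1.0, 0.5)
    K_range: tuple[float, float] = (0.1, 0.2)
    extinction_threshold: float = 1e-6
    # Typo-repair switches for ambiguities in the printed model; defaults
    # are the repaired readings.
    repair_growth_nutrient2: bool = True
    repair_denominator_weights: bool = True
    uptake_uses_basal_biomass: bool = True

    def with_temperature_C(self, temp_C: float) -> "ATNParameters":
        """Return a copy with simulation temperature set in Celsius."""
        return replace(self, T=temp_C + 273.15)

    @property
    def temperature_C(self) -> float:
        return self.T - 273.15


def arrhenius(E: float, T: float, T0: float = 293.15) -> float:
    """Boltzmann-Arrhenius factor ``exp(E (T0 - T) / (k T0 T))``.

    Equals exactly 1 at ``T == T0``. ``E`` in eV, temperatures in
    Kelvin. With this sign convention a negative ``E`` gives a factor
    above 1 for ``T > T0`` (rates rising with warming).
    """
    if T == T0:
        return 1.0
    return float(np.exp(E * (T0 - T) / (BOLTZMANN_EV * T0 * T)))


def ricker_niche(m_i, m_j, R_opt: float = 71.68, gamma_R: float = 2.0,
                 threshold: float = 0.01):
    """Hump-shaped feeding-niche probability of consumer ``m_i`` on prey ``m_j``.

    ``L = ((m_i / (m_j R_opt)) exp(1 - m_i / (m_j R_opt)))**gamma_R``,
    maximal (exactly 1) at the optimal mass ratio ``m_i/m_j = R_opt``,
    set to 0 below ``threshold``.
    """
    m_i = np.asarray(m_i, dtype=float)
    m_j = np.asarray(m_j, dtype=float)
    if np.any(m_i <= 0) or np.any(m_j <= 0):
        raise ValueError("body masses must be positive")
    u = m_i / (m_j * R_opt)
    L = (u * np.exp(1.0 - u)) ** gamma_R
    L = np.where(L < threshold, 0.0, L)
    return L if L.shape else float(L)


def metabolic_rate(m, T: float, params: ATNParameters):
    """Per-biomass metabolic rate ``x_i = x0 m^-0.25 * Arrhenius(E_x)``."""
    m = np.asarray(m, dtype=float)
    x = params.x0 * m ** -0.25 * arrhenius(params.E_x, T, params.T0)
    return x if x.shape else float(x)


@dataclass
class Community:
    """A mass-structured food web plus its drawn allometric constants.

    ``masses`` are body masses (arbitrary units); ``is_basal`` flags the
    producer compartment. ``beta_cons/beta_res`` and ``eta_cons/eta_res``
    are each species' encounter and handling exponents in its consumer
    and resource roles; ``c0_i`` the per-consumer interference constant.
    ``L`` is the thresholded Ricker niche matrix (predator rows), ``link``
    its boolean support, and ``K`` the (n_basal, 2) half-saturation
    matrix for nutrient uptake.
    """

    masses: np.ndarray
    is_basal: np.ndarray
    beta_cons: np.ndarray
    beta_res: np.ndarray
    eta_cons: np.ndarray
    eta_res: np.ndarray
    c0_i: np.ndarray
    L: np.ndarray
    link: np.ndarray
    K: np.ndarray

    @property
    def n_species(self) -> int:
        return self.masses.size

    @property
    def basal_indices(self) -> np.ndarray:
        return np.flatnonzero(self.is_basal)

    @property
    def consumer_indices(self) -> np.ndarray:
        return np.flatnonzero(~self.is_basal)

    def rate_matrices(self, params: ATNParameters):
        """Temperature-dependent encounter ``P``, capture ``b = P*L``,
        handling ``h`` matrices and interference vector ``c``."""
        m = self.masses
        arr_p = arrhenius(params.E_p, params.T, params.T0)
        arr_h = arrhenius(params.E_h, params.T, params.T0)
        arr_c = arrhenius(params.E_c, params.T, params.T0)
        P = (params.p0
             * (m[:, None] ** self.beta_cons[:, None])
             * (m[None, :] ** self.beta_res[None, :]) * arr_p)
        b = P * self.L
        h = (params.h0
             * (m[:, None] ** self.eta_cons[:, None])
             * (m[None, :] ** self.eta_res[None, :]) * arr_h)
        c = self.c0_i * arr_c
        return P, b, h, c

    def to_json(self, path) -> None:
        payload = {
            "masses": self.masses.tolist(),
            "is_basal": self.is_basal.astype(int).tolist(),
            "beta_cons": self.beta_cons.tolist(),
            "beta_res": self.beta_res.tolist(),
            "eta_cons": self.eta_cons.tolist(),
            "eta_res": self.eta_res.tolist(),
            "c0_i": self.c0_i.tolist(),
            "L": self.L.tolist(),
            "K": self.K.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "Community":
        with open(path) as fh:
            d = json.load(fh)
        L = np.asarray(d["L"], dtype=float)
        return cls(
            masses=np.asarray(d["masses"], dtype=float),
            is_basal=np.asarray(d["is_basal"], dtype=bool),
            beta_cons=np.asarray(d["beta_cons"], dtype=float),
            beta_res=np.asarray(d["beta_res"], dtype=float),
            eta_cons=np.asarray(d["eta_cons"], dtype=float),
            eta_res=np.asarray(d["eta_res"], dtype=float),
            c0_i=np.asarray(d["c0_i"], dtype=float),
            L=L,
            link=L > 0,
            K=np.asarray(d["K"], dtype=float),
        )


@dataclass
class ForagingPolicy:
    """How a consumer splits foraging effort across its linked prey.

    ``kind='static'``: effort is 1 over the number of prey species.
    ``kind='flexible'``: effort proportional to a skew-normal preference
    density over log10 prey mass, predicted per consumer from its log10
    body mass, the simulation temperature (Celsius) and log10 of its
    current total prey biomass; masked to the link structure and
    renormalized to sum to 1. ``update='dynamic'`` recomputes weights
    inside the RHS from the instantaneous state; ``update='at_start'``
    freezes them at the initial state.

    ``predictor`` must map (log10_mass, temp_C, log10_resource) to a
    callable density over log10 prey mass (see
    :func:`flexforage.selectivity_models.predict_preference_pdf`).
    """

    kind: str = "static"
    predictor: object | None = None
    update: str = "dynamic"

    def __post_init__(self):
        if self.kind not in ("static", "flexible"):
            raise ValueError(f"unknown policy kind {self.kind!r}")
        if self.kind == "flexible" and self.predictor is None:
            raise ValueError("flexible policy requires a predictor")
        if self.update not in ("dynamic", "at_start"):
            raise ValueError(f"unknown update mode {self.update!r}")


def _static_weights(link: np.ndarray) -> np.ndarray:
    n_prey = link.sum(axis=1)
    w = np.zeros(link.shape)
    rows = n_prey > 0
    w[rows] = link[rows] / n_prey[rows, None]
    return w


def _skewnorm_pdf(x, alpha, xi, omega):
    """Vectorized skew-normal density 2/w phi(z) Phi(alpha z)."""
    from scipy.special import ndtr

    z = (x - xi) / omega
    return (2.0 / omega) * np.exp(-0.5 * z * z) / np.sqrt(2 * np.pi) \
        * ndtr(alpha * z)


def foraging_weights(community: Community, policy: ForagingPolicy,
                     biomasses: np.ndarray | None = None,
                     temp_C: float | None = None) -> np.ndarray:
    """Row-stochastic effort matrix ``w`` over the community's links.

    Static policy: uniform 1/n over each consumer's prey. Flexible
    policy: the predicted skew-normal preference density evaluated at
    each linked prey's log10 body mass, renormalized per consumer; a
    consumer whose density vanishes on all its prey falls back to
    uniform effort. Predictors exposing vectorized ``parameters`` (for
    example :class:`~flexforage.selectivity_models.SkewNormalPredictor`)
    take a fast array path; any callable with the
    ``(log10_mass, temp_C, log10_resource) -> pdf`` signature works.
    """
    link = community.link
    if policy.kind == "static":
        return _static_weights(link)
    if biomasses is None or temp_C is None:
        raise ValueError("flexible weights need biomasses and temperature")
    B = np.maximum(np.asarray(biomasses, dtype=float), 0.0)
    log_mj = np.log10(community.masses)
    rows = np.flatnonzero(link.any(axis=1))
    log_resource = np.log10(np.maximum((link * B[None, :]).sum(axis=1),
                                       1e-12))
    if hasattr(policy.predictor, "parameters_arrays"):
        xi, omega, alpha = policy.predictor.parameters_arrays(
            log_mj[rows], temp_C, log_resource[rows])
        vals = _skewnorm_pdf(log_mj[None, :], alpha[:, None],
                             xi[:, None], omega[:, None])
        vals = np.where(link[rows], vals, 0.0)
        totals = vals.sum(axis=1)
        bad = ~np.isfinite(totals) | (totals <= 0.0)
        if bad.any():
            vals[bad] = link[rows[bad]].astype(float)
            totals = vals.sum(axis=1)
        w = np.zeros(link.shape)
        w[rows] = vals / totals[:, None]
        return w
    w = np.zeros(link.shape)
    for i in rows:
        prey = np.flatnonzero(link[i])
        pdf = policy.predictor(log_mj[i], temp_C, float(log_resource[i]))
        vals = np.asarray(pdf(log_mj[prey]), dtype=float)
        total = vals.sum()
        if not np.isfinite(total) or total <= 0.0:
            vals = np.ones(prey.size)
            total = vals.sum()
        w[i, prey] = vals / total
    return w


def functional_response(biomasses: np.ndarray, community: Community,
                        params: ATNParameters,
                        w: np.ndarray | None = None,
                        rates: tuple | None = None) -> np.ndarray:
    """Per-unit-consumer-biomass feeding rates ``F[i, j]``.

    ``F_ij = w_ij b_ij B_j^{1+q} / (1 + c_i B_i + sum_k w_ik h_ik b_ik
    B_k^{1+q}) / m_i`` with capture ``b = P * L``. The half-saturation
    sum runs over each consumer's own prey with its effort and handling
    weights (set ``params.repair_denominator_weights=False`` for the
    literal printed form with a per-prey ``w_ij`` factor outside an
    unweighted sum).
    """
    B = np.asarray(biomasses, dtype=float)
    if np.any(B < 0):
        raise ValueError("negative biomass")
    if w is None:
        w = _static_weights(community.link)
    if rates is None:
        _, b, h, c = community.rate_matrices(params)
    else:
        b, h, c = rates
    Bq = B ** (1.0 + params.q)
    if params.repair_denominator_weights:
        half_sat = (w * h * b) @ Bq                      # per consumer i
        denom = 1.0 + c * B + half_sat
        F = (w * b * Bq[None, :]) / denom[:, None]
    else:
        raw_sum = (h * b) @ Bq
        denom = 1.0 + c[:, None] * B[:, None] + w * raw_sum[:, None]
        with np.errstate(invalid="ignore", divide="ignore"):
            F = np.where(denom > 0, (w * b * Bq[None, :]) / denom, 0.0)
    F = F / community.masses[:, None]
    return F


def derivatives(state: np.ndarray, community: Community,
                params: ATNParameters,
                w: np.ndarray | None = None,
                alive: np.ndarray | None = None,
                rates: tuple | None = None) -> np.ndarray:
    """Right-hand side of the ATN system for ``state = [B_1..B_S, N_1, N_2]``.

    Consumers gain assimilated intake (``e_P`` on basal prey, ``e_A`` on
    animal prey), lose predation and metabolism. Basal species grow at
    ``r_i G_i B_i`` with ``r_i = m^-0.25 * Arrhenius(E_r)`` and a
    Liebig-minimum nutrient factor ``G_i``; nutrients are supplied by
    turnover ``D (S_l - N_l)`` and depleted by plant uptake.
    """
    state = np.asarray(state, dtype=float)
    if np.any(np.isnan(state)):
        raise ValueError("NaN in state")
    S = community.n_species
    B = np.maximum(state[:S], 0.0)
    N1, N2 = state[S], state[S + 1]
    if alive is not None:
        B = np.where(alive, B, 0.0)
    F = functional_response(B, community, params, w=w, rates=rates)
    x = params.x0 * community.masses ** -0.25 * arrhenius(
        params.E_x, params.T, params.T0)

    basal = community.is_basal
    gains = (params.e_P * F[:, basal].sum(axis=1)
             + params.e_A * F[:, ~basal].sum(axis=1)) * B
    pred_loss = F.T @ B          # sum_j B_j F_ji: loss of i to predators j
    dB = np.where(basal, 0.0, gains) - pred_loss - x * B

    r = community.masses ** -0.25 * arrhenius(params.E_r, params.T, params.T0)
    Kb = community.K
    Nmax1 = np.maximum(N1, 0.0)
    Nmax2 = np.maximum(N2, 0.0)
    g1 = Nmax1 / (Kb[:, 0] + Nmax1)
    second_num = Nmax2 if params.repair_growth_nutrient2 else Nmax1
    g2 = second_num / (Kb[:, 1] + second_num)
    G = np.minimum(g1, g2)
    bi = community.basal_indices
    growth = r[bi] * G * B[bi]
    dB[bi] += growth

    uptake_carrier = B[bi] if params.uptake_uses_basal_biomass else np.ones_like(B[bi])
    uptake = (r[bi] * G * uptake_carrier).sum()
    dN1 = params.D * (params.S[0] - N1) - params.v[0] * uptake
    dN2 = params.D * (params.S[1] - N2) - params.v[1] * uptake

    if alive is not None:
        dB = np.where(alive, dB, 0.0)
    return np.concatenate([dB, [dN1, dN2]])


@dataclass
class SimulationResult:
    """Trajectory, final state and extinction record of one run."""

    t: np.ndarray
    biomasses: np.ndarray          # (n_times, n_species)
    nutrients: np.ndarray          # (n_times, 2)
    extinct: dict[int, float] = field(default_factory=dict)  # species -> time

    @property
    def final_biomasses(self) -> np.ndarray:
        return self.biomasses[-1]

    def extinction_counts(self, community: Community) -> tuple[int, int]:
        """(consumers extinct, basal extinct)."""
        cons = sum(1 for i in self.extinct if not community.is_basal[i])
        bas = sum(1 for i in self.extinct if community.is_basal[i])
        return cons, bas


def simulate(community: Community, params: ATNParameters,
             policy: ForagingPolicy | None = None,
             B0: np.ndarray | None = None,
             N0: tuple[float, float] | None = None,
             t_end: float = 1e5,
             n_record: int = 200,
             rtol: float = 1e-8, atol: float = 1e-12,
             method: str = "LSODA") -> SimulationResult:
    """Integrate the community to ``t_end`` with extinction clamping.

    Species whose biomass crosses ``params.extinction_threshold`` from
    above are clamped to zero, recorded with their crossing time and
    excluded from the dynamics thereafter (they never resurrect). The
    integrator is restarted after each clamping event. For the flexible
    policy in ``dynamic`` mode the effort matrix is recomputed inside
    the RHS from the instantaneous state; in ``at_start`` mode it is
    frozen at the initial state.
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    policy = policy or ForagingPolicy("static")
    S = community.n_species
    if B0 is None:
        raise ValueError("initial biomasses B0 are required")
    B0 = np.asarray(B0, dtype=float)
    if N0 is None:
        N0 = (params.S[0] / 2.0, params.S[1] / 2.0)
    y = np.concatenate([B0, np.asarray(N0, dtype=float)])
    temp_C = params.temperature_C

    alive = np.ones(S, dtype=bool)
    extinct: dict[int, float] = {}
    theta = params.extinction_threshold

    static_w = _static_weights(community.link)
    frozen_w = None
    if policy.kind == "flexible" and policy.update == "at_start":
        frozen_w = foraging_weights(community, policy, B0, temp_C)

    def current_w(B):
        if policy.kind == "static":
            return static_w
        if frozen_w is not None:
            return frozen_w
        return foraging_weights(community, policy, B, temp_C)

    _, b_mat, h_mat, c_vec = community.rate_matrices(params)
    rates = (b_mat, h_mat, c_vec)

    def rhs(t, yv):
        w = current_w(yv[:S])
        return derivatives(yv, community, params, w=w, alive=alive,
                           rates=rates)

    def extinction_event(t, yv):
        live = yv[:S][alive]
        if live.size == 0:
            return 1.0
        return float(live.min() - theta)

    extinction_event.terminal = True
    extinction_event.direction = -1

    t_now = 0.0
    ts = [0.0]
    states = [y.copy()]
    record_grid = np.linspace(0.0, t_end, n_record + 1)[1:]

    while t_now < t_end:
        t_eval = record_grid[record_grid > t_now + 1e-12]
        sol = solve_ivp(rhs, (t_now, t_end), y, method=method,
                        events=extinction_event, rtol=rtol, atol=atol,
                        t_eval=t_eval if t_eval.size else None)
        if not sol.success and sol.status != 1:
            raise RuntimeError(f"integration failed: {sol.message}")
        sol_t = np.asarray(sol.t, dtype=float)
        if sol_t.size:
            ts.extend(sol_t.tolist())
            states.extend(np.asarray(sol.y).T.copy())
        if sol.status == 1:  # extinction event
            t_event = float(sol.t_events[0][0])
            y = sol.y_events[0][0].copy()
            newly = alive & (y[:S] <= theta * (1 + 1e-9))
            for idx in np.flatnonzero(newly):
                extinct[int(idx)] = t_event
            alive &= ~newly
            y[:S] = np.where(alive, np.maximum(y[:S], 0.0), 0.0)
            ts.append(t_event)
            states.append(y.copy())
            t_now = t_event
            if not alive.any():
                # only nutrients left; their relaxation is closed-form,
                # integrate once more without events
                sol2 = solve_ivp(rhs, (t_now, t_end), y, method=method,
                                 rtol=rtol, atol=atol)
                ts.append(float(sol2.t[-1]))
                states.append(sol2.y[:, -1].copy())
                break
        else:
            y = np.asarray(sol.y)[:, -1] if sol_t.size else y
            if not sol_t.size or sol_t[-1] < t_end - 1e-9:
                # t_eval empty near the end; take final solver state
                solf = solve_ivp(rhs, (t_now, t_end), y, method=method,
                                 events=extinction_event, rtol=rtol, atol=atol)
                if solf.status == 1:
                    t_now = float(solf.t_events[0][0])
                    y = solf.y_events[0][0].copy()
                    newly = alive & (y[:S] <= theta * (1 + 1e-9))
                    for idx in np.flatnonzero(newly):
                        extinct[int(idx)] = t_now
                    alive &= ~newly
                    y[:S] = np.where(alive, np.maximum(y[:S], 0.0), 0.0)
                    ts.append(t_now)
                    states.append(y.copy())
                    continue
                y = solf.y[:, -1]
            ts.append(t_end)
            states.append(y.copy())
            break

    arr = np.asarray(states)
    t_arr = np.asarray(ts)
    order = np.argsort(t_arr, kind="stable")
    t_arr, arr = t_arr[order], arr[order]
    return SimulationResult(t=t_arr, biomasses=arr[:, :S],
                            nutrients=arr[:, S:], extinct=extinct)
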