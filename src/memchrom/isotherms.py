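"""Batch-adsorption interpretation and salt-dependent competitive Langmuir isotherms.

Static binding capacities are measured in finite-bath (shake) experiments:
a membrane coupon of volume ``V_ads`` equilibrates with ``V_total`` of
liquid.  Two independent mass balances give the loading q (g per L of
membrane bed volume):

    binding:  q_i = (c_feed,i - c*_i) * V_total / V_ads
    elution:  q_i = c*_i * V_total / V_ads

For process simulation the equilibrium is described by an extended
competitive Langmuir model whose Henry coefficient and saturation capacity
depend on the modifier (salt) concentration:

    q_i = H_i c_i / (1 + sum_j (H_j / qmax_j) c_j) + L1 cmod c_i
    qmax_i = a1_i cmod + a2_i
    H_i    = b1_i cmod ** b2_i

The linear ``L1`` term is only needed for hydrophobic-interaction media,
where loading keeps rising with salt beyond Langmuir saturation; for
ion-exchange media L1 = 0.  The modifier itself does not compete for
binding sites: its influence enters exclusively through qmax(cmod) and
H(cmod).  Transport into the membrane is lumped into a single linear
driving-force coefficient ``kla`` (1/min).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "BatchAdsorptionPoint",
    "IsothermDataset",
    "IsothermParams",
    "IsothermFitResult",
    "loading_from_binding",
    "loading_from_elution",
    "q_equilibrium",
    "fit_isotherm",
]

_MASS_BALANCE_TOL = 1e-6  # g/L slack on c* <= c_feed checks


@dataclass(frozen=True)
class BatchAdsorptionPoint:
    """One finite-bath equilibrium point.

    Concentrations are per-component arrays aligned with ``names``;
    ``c_star_binding`` is the supernatant after the binding step,
    ``c_star_elution`` the supernatant after stripping the membrane into a
    fresh bath of volume ``V_total``.
    """

    names: tuple[str, ...]
    c_feed: np.ndarray  # g/L
    c_star_binding: np.ndarray  # g/L
    c_star_elution: np.ndarray  # g/L
    v_total: float  # mL
    v_ads: float  # mL, membrane coupon volume
    c_mod: float  # mol/L during binding

    def __post_init__(self) -> None:
        for attr in ("c_feed", "c_star_binding", "c_star_elution"):
            arr = np.asarray(getattr(self, attr), dtype=float)
            object.__setattr__(self, attr, arr)
            if arr.shape != (len(self.names),):
                raise ValueError(f"{attr} must have one value per component name")
            if np.any(arr < 0):
                raise ValueError(f"{attr} must be >= 0")
        if self.v_total <= 0 or self.v_ads <= 0:
            raise ValueError("V_total and V_ads must be > 0")
        if np.any(self.c_star_binding > self.c_feed + _MASS_BALANCE_TOL * np.maximum(self.c_feed, 1.0) + 1e-9):
            raise ValueError("supernatant exceeds feed concentration; check sample assignment")


@dataclass(frozen=True)
class IsothermDataset:
    points: tuple[BatchAdsorptionPoint, ...]
    resin_label: str = "IEX"  # "IEX" or "HIC"

    def __post_init__(self) -> None:
        if not self.points:
            raise ValueError("dataset must contain at least one point")
        names = self.points[0].names
        if any(p.names != names for p in self.points):
            raise ValueError("all points must share the same component names")

    @property
    def names(self) -> tuple[str, ...]:
        return self.points[0].names

    @property
    def modifier_levels(self) -> np.ndarray:
        return np.unique([p.c_mod for p in self.points])


@dataclass(frozen=True)
class IsothermParams:
    """Salt-dependent competitive Langmuir parameters for ``n`` components.

    ``a1``/``a2`` parameterise qmax(cmod) = a1*cmod + a2 (g/L-membrane per
    mol/L and g/L-membrane); ``b1``/``b2`` the Henry power law
    H(cmod) = b1*cmod**b2; ``l1`` the linear HIC term (L/g per mol/L,
    0 for ion exchange); ``kla`` the lumped mass-transfer coefficient in
    1/min.
    """

    a1: np.ndarray
    a2: np.ndarray
    b1: np.ndarray
    b2: np.ndarray
    l1: float = 0.0
    kla: float = 6.0  # 1/min
    modifier_range: tuple[float, float] = (1e-3, 1.0)  # mol/L validity window

    def __post_init__(self) -> None:
        for attr in ("a1", "a2", "b1", "b2"):
            object.__setattr__(self, attr, np.atleast_1d(np.asarray(getattr(self, attr), dtype=float)))
        n = len(self.a1)
        if any(len(getattr(self, a)) != n for a in ("a2", "b1", "b2")):
            raise ValueError("a1, a2, b1, b2 must have equal length")
        if self.kla <= 0:
            raise ValueError("kla must be > 0")
        lo, hi = self.modifier_range
        for c_mod in (max(lo, 1e-12), hi):
            if np.any(self.qmax(c_mod) <= 0):
                raise ValueError(
                    f"qmax(cmod) must stay > 0 over the modifier range {self.modifier_range}"
                )
        if np.any(self.b1 < 0):
            raise ValueError("b1 must be >= 0 (H >= 0)")

    @property
    def n_components(self) -> int:
        return len(self.a1)

    def qmax(self, c_mod) -> np.ndarray:
        """Saturation capacity per component at modifier level(s) cmod."""
        c_mod = np.asarray(c_mod, dtype=float)
        return np.outer(c_mod, self.a1).squeeze() + self.a2 if c_mod.ndim else self.a1 * c_mod + self.a2

    def henry(self, c_mod) -> np.ndarray:
        """Henry coefficient per component at modifier level(s) cmod."""
        c_mod = np.maximum(np.asarray(c_mod, dtype=float), 1e-12)
        if c_mod.ndim:
            return self.b1 * c_mod[..., None] ** self.b2
        return self.b1 * c_mod**self.b2


def loading_from_binding(point: BatchAdsorptionPoint, index: int) -> float:
    """Loading of component ``index`` from the binding-step mass balance."""
    q = (point.c_feed[index] - point.c_star_binding[index]) * point.v_total / point.v_ads
    if q < -_MASS_BALANCE_TOL * point.v_total / point.v_ads:
        raise ValueError(
            f"negative loading ({q:.3g} g/L) for component {point.names[index]!r}; "
            "feed and supernatant samples may be swapped"
        )
    return max(q, 0.0)


def loading_from_elution(point: BatchAdsorptionPoint, index: int) -> float:
    """Loading of component ``index`` from the elution-step mass balance."""
    return point.c_star_elution[index] * point.v_total / point.v_ads


def q_equilibrium(c, c_mod, params: IsothermParams) -> np.ndarray:
    """Equilibrium loading for liquid concentrations ``c`` at salt ``c_mod``.

    ``c`` may be a single composition ``(n,)`` or a batch ``(m, n)``;
    ``c_mod`` a scalar or ``(m,)``.  Only non-modifier components enter the
    competitive denominator.
    """
    c = np.asarray(c, dtype=float)
    single = c.ndim == 1
    c2 = np.atleast_2d(c)
    c_mod_arr = np.broadcast_to(np.asarray(c_mod, dtype=float), (c2.shape[0],)).astype(float)
    if np.any(c2 < 0):
        raise ValueError("concentrations must be >= 0")
    qmax = np.atleast_2d(params.qmax(c_mod_arr))
    if np.any(qmax <= 0):
        bad = c_mod_arr[np.any(np.atleast_2d(params.qmax(c_mod_arr)) <= 0, axis=-1)]
        raise ValueError(
            f"qmax(cmod) <= 0 at cmod={bad[:3]}; outside the declared modifier "
            f"range {params.modifier_range}"
        )
    h = np.atleast_2d(params.henry(c_mod_arr))
    denom = 1.0 + np.sum(h / qmax * c2, axis=1, keepdims=True)
    q = h * c2 / denom + params.l1 * c_mod_arr[:, None] * c2
    return q[0] if single else q


@dataclass(frozen=True)
class IsothermFitResult:
    params: IsothermParams
    residual_norm: float
    residuals: np.ndarray  # per (point, component)
    n_starts: int


def _initial_guess(c_star, q_meas, c_mod, n: int) -> tuple[np.ndarray, ...]:
    """Per-level Scatchard estimates regressed against cmod.

    For each modifier level a single-component Langmuir is linearised as
    1/q = 1/(H c) + 1/qmax per component (competition ignored); the
    level-wise H and qmax are then regressed onto the power law / linear
    salt laws to seed the joint fit.
    """
    levels = np.unique(c_mod)
    h_lv = np.full((len(levels), n), np.nan)
    qm_lv = np.full((len(levels), n), np.nan)
    for m, lv in enumerate(levels):
        sel = c_mod == lv
        for i in range(n):
            c_i, q_i = c_star[sel, i], q_meas[sel, i]
            ok = (c_i > 1e-9) & (q_i > 1e-9)
            if ok.sum() >= 2:
                A = np.column_stack([1.0 / c_i[ok], np.ones(ok.sum())])
                coef, *_ = np.linalg.lstsq(A, 1.0 / q_i[ok], rcond=None)
                if coef[0] > 0:
                    h_lv[m, i] = 1.0 / coef[0]
                if coef[1] > 0:
                    qm_lv[m, i] = 1.0 / coef[1]
            if not np.isfinite(h_lv[m, i]) and ok.any():
                h_lv[m, i] = np.median(q_i[ok] / c_i[ok])
            if not np.isfinite(qm_lv[m, i]) and ok.any():
                qm_lv[m, i] = 2.0 * q_i[ok].max()
    h_lv = np.where(np.isfinite(h_lv) & (h_lv > 0), h_lv, np.nanmax(h_lv, initial=1.0))
    qm_lv = np.where(np.isfinite(qm_lv) & (qm_lv > 0), qm_lv, np.nanmax(qm_lv, initial=100.0))
    # Henry power law: log H = log b1 + b2 log cmod
    log_cm = np.log(np.maximum(levels, 1e-12))
    A = np.column_stack([np.ones(len(levels)), log_cm])
    b1 = np.empty(n)
    b2 = np.empty(n)
    a1 = np.empty(n)
    a2 = np.empty(n)
    for i in range(n):
        coef, *_ = np.linalg.lstsq(A, np.log(h_lv[:, i]), rcond=None)
        b1[i], b2[i] = np.exp(coef[0]), coef[1]
        coef, *_ = np.linalg.lstsq(np.column_stack([levels, np.ones(len(levels))]), qm_lv[:, i], rcond=None)
        a1[i], a2[i] = coef
        if a2[i] <= 0:
            a1[i], a2[i] = 0.0, max(np.median(qm_lv[:, i]), 1.0)
    return a1, a2, b1, b2


def fit_isotherm(
    dataset: IsothermDataset,
    n_components: int | None = None,
    fit_l1: bool | None = None,
    kla: float = 6.0,
    n_starts: int = 5,
    seed: int = 0,
    loading: str = "both",
) -> IsothermFitResult:
    """Least-squares fit of the salt-dependent Langmuir parameters.

    Minimises the weighted squared deviation between modelled and measured
    loadings over all points and components, with the model evaluated at the
    measured supernatant concentrations.  ``loading`` selects the
    measurement route: ``"binding"``, ``"elution"`` or ``"both"`` (default;
    the two mass balances are combined with inverse-variance weights under
    multiplicative measurement noise — the binding balance is precise where
    depletion is strong, the elution balance everywhere else).  Because the
    Henry power law creates local minima, ``n_starts`` perturbed restarts
    (seeded) around a Scatchard-based initial guess are performed and the
    best solution returned.

    ``fit_l1`` defaults to True for datasets labelled HIC, False otherwise.
    """
    names = dataset.names
    n = n_components if n_components is not None else len(names)
    if fit_l1 is None:
        fit_l1 = dataset.resin_label.upper() == "HIC"

    levels = dataset.modifier_levels
    if len(levels) < 2:
        raise ValueError(
            "at least two distinct modifier levels are required to fit the salt laws; "
            "fix b2/a1 or add levels"
        )
    c_star = np.array([p.c_star_binding[:n] for p in dataset.points])
    q_bind = np.array([[loading_from_binding(p, i) for i in range(n)] for p in dataset.points])
    q_elu = np.array([[loading_from_elution(p, i) for i in range(n)] for p in dataset.points])
    phase = np.array([p.v_total / p.v_ads for p in dataset.points])[:, None]
    if loading == "binding":
        q_meas = q_bind
    elif loading == "elution":
        q_meas = q_elu
    elif loading == "both":
        q_meas = q_elu  # elution balance anchors the point estimates below
    else:
        raise ValueError("loading must be 'binding', 'elution' or 'both'")
    c_mod = np.array([p.c_mod for p in dataset.points])
    conc_levels = {tuple(np.round(row, 9)) for row in c_star}
    if len(conc_levels) < 2:
        raise ValueError("at least two distinct concentration levels are required")

    # declared validity window = observed salt window
    mod_range = (float(levels.min()), float(levels.max()))
    a1, a2, b1, b2 = _initial_guess(c_star, q_meas, c_mod, n)
    x0 = np.concatenate([a1, a2, np.log(np.maximum(b1, 1e-12)), b2])
    if fit_l1:
        x0 = np.append(x0, 0.01)

    cm_lo, cm_hi = float(levels.min()), float(levels.max())
    # Inverse-variance weighting under multiplicative measurement noise:
    # sd(q from elution) ~ q itself; sd(q from binding) ~ c* x V_total/V_ads.
    # Floors at 2% of the per-component maximum keep zero-loading points finite.
    floor = 0.02 * np.maximum(np.abs(q_elu).max(axis=0), 1e-6)
    scale_elu = np.maximum(np.abs(q_elu), floor)
    scale_bind = np.maximum(c_star * phase, floor)
    if loading == "binding":
        targets = [(q_bind, np.maximum(np.abs(q_bind), floor))]
    elif loading == "elution":
        targets = [(q_elu, scale_elu)]
    else:
        targets = [(q_elu, scale_elu), (q_bind, scale_bind)]

    def residual(x: np.ndarray) -> np.ndarray:
        a1x, a2x = x[:n], x[n : 2 * n]
        b1x, b2x = np.exp(x[2 * n : 3 * n]), x[3 * n : 4 * n]
        l1x = x[4 * n] if fit_l1 else 0.0
        qmax = np.maximum(c_mod[:, None] * a1x + a2x, 1e-9)
        h = b1x * np.maximum(c_mod, 1e-12)[:, None] ** b2x
        denom = 1.0 + np.sum(h / qmax * c_star, axis=1, keepdims=True)
        q_model = h * c_star / denom + l1x * c_mod[:, None] * c_star
        res = np.concatenate([((q_model - qm) / sc).ravel() for qm, sc in targets])
        # soft penalty keeping qmax positive across the observed salt window
        qmax_edges = np.concatenate([cm_lo * a1x + a2x, cm_hi * a1x + a2x])
        penalty = np.minimum(qmax_edges, 0.0) * 10.0
        return np.concatenate([res, penalty])

    lower = np.concatenate([np.full(n, -np.inf), np.full(n, 1e-9), np.full(n, -25.0), np.full(n, -10.0)])
    upper = np.concatenate([np.full(n, np.inf)] * 2 + [np.full(n, 25.0), np.full(n, 10.0)])
    if fit_l1:
        lower = np.append(lower, 0.0)
        upper = np.append(upper, np.inf)

    rng = np.random.default_rng(seed)
    best = None
    for start in range(max(1, n_starts)):
        x_start = x0.copy()
        if start > 0:
            x_start[: 2 * n] *= rng.lognormal(0.0, 0.3, 2 * n)
            x_start[2 * n : 3 * n] += rng.normal(0.0, 0.5, n)
            x_start[3 * n : 4 * n] += rng.normal(0.0, 0.3, n)
        x_start = np.clip(x_start, lower + 1e-12, upper - 1e-12 if np.all(np.isfinite(upper)) else upper)
        try:
            sol = least_squares(
                residual, x_start, bounds=(lower, upper), method="trf",
                xtol=1e-15, ftol=1e-15, gtol=1e-15, max_nfev=4000,
            )
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError("isotherm fit failed from every start")

    x = best.x
    params = IsothermParams(
        a1=x[:n], a2=x[n : 2 * n], b1=np.exp(x[2 * n : 3 * n]), b2=x[3 * n : 4 * n],
        l1=float(x[4 * n]) if fit_l1 else 0.0, kla=kla, modifier_range=mod_range,
    )
    res = residual(x)[: q_meas.size].reshape(q_meas.shape) * targets[0][1]
    return IsothermFitResult(
        params=params, residual_norm=float(np.sqrt(np.sum(res**2))),
        residuals=res, n_starts=max(1, n_starts),
    )
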