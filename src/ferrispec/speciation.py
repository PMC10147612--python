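"""Ferric-iron speciation among transferrin, a chelator, and free iron.

The model system is a culture medium containing transferrin T with two
sequential iron-binding sites,

    T    + Fe3+ <=> TFe     K1 = [TFe]  / ([T][Fe3+])
    TFe  + Fe3+ <=> TFe2    K2 = [TFe2] / ([TFe][Fe3+])

(the two monoferric lobe species are lumped into one pool, since only
the sequential macroscopic constants are available), plus an optional
chelator L forming cumulative complexes FeL_i governed by conditional
beta_i' at the medium pH (see :mod:`ferrispec.chelators`).  K1 and K2
are conditional constants valid at pH 7.4 / 3.5 mmol/L bicarbonate and
are not pH-corrected.

Given total pools (fe_total, tf_total, ligand_total) the solver finds
free [Fe3+] = f and free [L] = l such that the two nonlinear mass
balances hold:

    iron:    f + T(f)*(K1 f + 2 K1 K2 f^2) + sum_i beta_i' f l^i = fe_total
    ligand:  l + sum_i i beta_i' f l^i                           = ligand_total

with T(f) = tf_total / (1 + K1 f + K1 K2 f^2).  Both residuals are
strictly increasing in their own variable, which makes a nested
bisection in (log f, log l) a guaranteed fallback behind the fast
damped-Newton iteration used by default.  Free iron spans ~25 orders of
magnitude across compositions of interest, so all root-finding happens
in log space.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .chelators import ChelatorDefinition, effective_betas
from .errors import SolverError, ValidationError

__all__ = [
    "TransferrinParameters",
    "MediumComposition",
    "SpeciationState",
    "solve_equilibrium",
    "tf_fractions",
    "compute_pfe",
    "CONC_FLOOR",
]

#: Concentration floor (mol/L) keeping logarithms finite for empty pools.
CONC_FLOOR = 1e-30


@dataclass(frozen=True)
class TransferrinParameters:
    """Conditional iron-binding constants and molar-mass conventions.

    ``k1``/``k2`` are the sequential association constants for the first
    and second ferric ion (L/mol, conditional at pH 7.4, 3.5 mmol/L
    bicarbonate).  Two molar masses coexist deliberately:
    ``molar_mass_equivalence`` (76,900 g/mol) reproduces the medium
    equivalence 1000 ug/mL transferrin = 26 umol/L chelatable iron and
    is used for concentration conversions, while ``molar_mass_budget``
    (80,000 g/mol, the nominal ~80 kDa) is used for per-cell mass
    budgets.  The two conventions differ by ~4% and are kept separate
    rather than averaged.
    """

    k1: float = 7.0e22
    k2: float = 3.6e21
    molar_mass_equivalence: float = 76_900.0
    molar_mass_budget: float = 80_000.0
    iron_sites: int = 2

    def __post_init__(self):
        if not (self.k1 > self.k2 > 0):
            raise ValidationError(f"need k1 > k2 > 0, got k1={self.k1}, k2={self.k2}")
        if self.molar_mass_equivalence <= 0 or self.molar_mass_budget <= 0:
            raise ValidationError("molar masses must be positive")
        if self.iron_sites != 2:
            raise ValidationError("transferrin has exactly two iron sites")


@dataclass(frozen=True)
class MediumComposition:
    """Total component pools of a culture medium (all mol/L).

    ``fe_total`` counts every iron atom regardless of speciation;
    ``ligand_total`` counts chelator monomers (three per Def3Fe
    complex).  ``ph`` and ``bicarbonate`` are recorded conditions — the
    binding constants are assumed valid at them.
    """

    tf_total: float
    fe_total: float
    ligand_total: float = 0.0
    ph: float = 7.4
    bicarbonate: float = 3.5e-3

    def __post_init__(self):
        for name in ("tf_total", "fe_total", "ligand_total"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValidationError(f"{name} must be finite and >= 0, got {v}")
        if not 0.0 < self.ph < 14.0:
            raise ValidationError(f"ph must lie in (0, 14), got {self.ph}")
        if self.bicarbonate < 0:
            raise ValidationError("bicarbonate must be >= 0")


@dataclass(frozen=True)
class SpeciationState:
    """Solved per-species concentrations (mol/L) at equilibrium.

    ``complexes[i-1]`` holds [FeL_i].  Derived transferrin fractions are
    exposed as properties and via :func:`tf_fractions`.
    """

    free_fe: float
    free_ligand: float
    tf0: float
    tf1: float
    tf2: float
    complexes: tuple[float, ...]

    @property
    def tf_total(self) -> float:
        return self.tf0 + self.tf1 + self.tf2

    @property
    def fe_total(self) -> float:
        """Total iron implied by the state (free + bound)."""
        chel = sum(self.complexes)
        return self.free_fe + self.tf1 + 2.0 * self.tf2 + chel

    @property
    def ligand_total(self) -> float:
        return self.free_ligand + sum(
            (i + 1) * c for i, c in enumerate(self.complexes)
        )

    @property
    def frac_apo(self) -> float:
        return tf_fractions(self, self.tf_total)[0]

    @property
    def frac_mono(self) -> float:
        return tf_fractions(self, self.tf_total)[1]

    @property
    def frac_holo(self) -> float:
        return tf_fractions(self, self.tf_total)[2]

    @property
    def tf_site_saturation(self) -> float:
        return tf_fractions(self, self.tf_total)[3]

    def as_dict(self) -> dict[str, float]:
        d = {
            "free_fe": self.free_fe,
            "free_ligand": self.free_ligand,
            "tf_apo": self.tf0,
            "tf_mono": self.tf1,
            "tf_holo": self.tf2,
        }
        for i, c in enumerate(self.complexes, start=1):
            d[f"fe_l{i}"] = c
        return d


def tf_fractions(
    state: SpeciationState, tf_total: float
) -> tuple[float, float, float, float]:
    """Apo/mono/holo fractions of total transferrin plus site saturation.

    Site saturation is iron-occupied sites over all sites,
    (tf1 + 2 tf2) / (2 tf_total).  Raises for ``tf_total == 0`` instead
    of returning NaN.
    """
    if not tf_total > 0:
        raise ValidationError(
            "transferrin fractions are undefined for tf_total = 0"
        )
    fa = state.tf0 / tf_total
    fm = state.tf1 / tf_total
    fh = state.tf2 / tf_total
    sat = (state.tf1 + 2.0 * state.tf2) / (2.0 * tf_total)
    return fa, fm, fh, sat


# ---------------------------------------------------------------------------
# solver internals
# ---------------------------------------------------------------------------


def _tf_bound_iron(f: float, tf_total: float, k1: float, k2: float) -> float:
    u = k1 * f
    v = k1 * k2 * f * f
    return tf_total * (u + 2.0 * v) / (1.0 + u + v)


def _species(f, l, tf_total, k1, k2, betas):
    denom = 1.0 + k1 * f + k1 * k2 * f * f
    tf0 = tf_total / denom
    tf1 = tf0 * k1 * f
    tf2 = tf1 * k2 * f
    complexes = tuple(b * f * l ** (i + 1) for i, b in enumerate(betas))
    return tf0, tf1, tf2, complexes


def _solve_ligand_given_fe(f, ligand_total, betas, rtol):
    """Inner 1-D solve of the ligand balance for fixed free iron.

    The residual l + sum i beta_i f l^i - ligand_total is strictly
    increasing in l, bracketed by (0, ligand_total]."""
    if ligand_total <= CONC_FLOOR:
        return 0.0

    def res(l):
        return l + sum(
            (i + 1) * b * f * l ** (i + 1) for i, b in enumerate(betas)
        ) - ligand_total

    lo, hi = math.log(CONC_FLOOR), math.log(ligand_total)
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if res(math.exp(mid)) > 0.0:
            hi = mid
        else:
            lo = mid
        if hi - lo < 1e-13:
            break
    l = math.exp(0.5 * (lo + hi))
    # Newton polish in log space (residual is smooth and increasing)
    for _ in range(8):
        r = res(l)
        dr = l + sum(
            (i + 1) ** 2 * b * f * l ** (i + 1) for i, b in enumerate(betas)
        )  # d res / d ln l
        if dr == 0.0:
            break
        l *= math.exp(max(min(-r / dr, 1.0), -1.0))
        if abs(r) <= rtol * ligand_total * 1e-3:
            break
    return l


def _solve_fe_only(fe_total, tf_total, k1, k2, rtol):
    """1-D bisection plus Newton polish on log free iron (no chelator)."""
    def res(f):
        return f + _tf_bound_iron(f, tf_total, k1, k2) - fe_total

    if res(fe_total) <= 0:  # no transferrin capture
        return fe_total
    lo, hi = math.log(CONC_FLOOR), math.log(fe_total)
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if res(math.exp(mid)) > 0.0:
            hi = mid
        else:
            lo = mid
        if hi - lo < 1e-13:
            break
    f = math.exp(0.5 * (lo + hi))
    for _ in range(8):
        r = res(f)
        u = k1 * f
        v = k1 * k2 * f * f
        d = 1.0 + u + v
        dtffe = tf_total * ((u + 4.0 * v) * d - (u + 2.0 * v) ** 2) / (d * d)
        dr = f + dtffe  # d res / d ln f
        if dr == 0.0:
            break
        f *= math.exp(max(min(-r / dr, 1.0), -1.0))
        if abs(r) <= rtol * fe_total * 1e-3:
            break
    return f


def _newton_2d(
    fe_total, ligand_total, tf_total, k1, k2, betas, rtol, max_iter,
    start=None,
):
    """Damped Newton on x=ln f, y=ln l with analytic Jacobian.

    Residuals are the log-ratios ln(balance/total), so convergence in
    the residual norm is convergence in relative terms.  Returns
    (f, l) or None when the iteration stalls.  ``start`` overrides the
    composition-derived initial guess (used to polish the bisection
    fallback).
    """
    if start is not None:
        x, y = math.log(start[0]), math.log(start[1])
    else:
        # composition-derived initial guess: ligand left after maximal
        # complexation, iron split against the dominant sink
        n = len(betas)
        fe_complexed = min(fe_total, ligand_total / n) if n else 0.0
        l0 = max(ligand_total - n * fe_complexed, ligand_total * 1e-9, CONC_FLOOR)
        guess_f = fe_total * 1e-12
        if betas and fe_complexed > 0:
            guess_f = fe_complexed / (betas[-1] * l0 ** n + 1.0 / fe_total)
        x = math.log(max(min(guess_f, fe_total), CONC_FLOOR * 1e5))
        y = math.log(max(min(l0, ligand_total), CONC_FLOOR * 1e5))

    def residuals(x, y):
        f, l = math.exp(x), math.exp(y)
        c = [b * f * l ** (i + 1) for i, b in enumerate(betas)]
        u = k1 * f
        v = k1 * k2 * f * f
        d = 1.0 + u + v
        tffe = tf_total * (u + 2.0 * v) / d
        f1 = f + tffe + sum(c)
        f2 = l + sum((i + 1) * ci for i, ci in enumerate(c))
        r1 = math.log(f1 / fe_total)
        r2 = math.log(f2 / ligand_total)
        # analytic Jacobian of (r1, r2) wrt (x, y)
        dtffe_dx = tf_total * ((u + 4.0 * v) * d - (u + 2.0 * v) ** 2) / (d * d)
        sc = sum(c)
        sic = sum((i + 1) * ci for i, ci in enumerate(c))
        si2c = sum((i + 1) ** 2 * ci for i, ci in enumerate(c))
        j11 = (f + dtffe_dx + sc) / f1
        j12 = sic / f1
        j21 = sic / f2
        j22 = (l + si2c) / f2
        return r1, r2, j11, j12, j21, j22

    # aim two decades below the promised tolerance so the returned
    # state's balances sit comfortably inside rtol
    target = rtol * 1e-2
    r1, r2, j11, j12, j21, j22 = residuals(x, y)
    norm = max(abs(r1), abs(r2))
    for _ in range(max_iter):
        if norm <= target:
            return math.exp(x), math.exp(y)
        det = j11 * j22 - j12 * j21
        if det == 0.0 or not math.isfinite(det):
            return None
        dx = -(j22 * r1 - j12 * r2) / det
        dy = -(-j21 * r1 + j11 * r2) / det
        # cap the log-space step; free iron can be 20+ decades off
        cap = 8.0
        scale = max(1.0, abs(dx) / cap, abs(dy) / cap)
        dx /= scale
        dy /= scale
        step = 1.0
        for _bt in range(60):
            try:
                t1, t2, t11, t12, t21, t22 = residuals(x + step * dx, y + step * dy)
            except (OverflowError, ValueError):
                step *= 0.5
                continue
            tnorm = max(abs(t1), abs(t2))
            if tnorm < norm or tnorm <= target:
                x, y = x + step * dx, y + step * dy
                r1, r2, j11, j12, j21, j22 = t1, t2, t11, t12, t21, t22
                norm = tnorm
                break
            step *= 0.5
        else:
            # stalled (likely at floating-point noise); accept if the
            # promised tolerance is already met
            return (math.exp(x), math.exp(y)) if norm <= rtol else None
    return (math.exp(x), math.exp(y)) if norm <= rtol else None


def _nested_bisection(fe_total, ligand_total, tf_total, k1, k2, betas, rtol):
    """Guaranteed fallback: outer bisection on log f, inner on log l."""
    def outer_res(f):
        l = _solve_ligand_given_fe(f, ligand_total, betas, rtol)
        chel = sum(b * f * l ** (i + 1) for i, b in enumerate(betas))
        return f + _tf_bound_iron(f, tf_total, k1, k2) + chel - fe_total

    lo, hi = math.log(CONC_FLOOR), math.log(fe_total)
    for _ in range(300):
        mid = 0.5 * (lo + hi)
        if outer_res(math.exp(mid)) > 0.0:
            hi = mid
        else:
            lo = mid
        if hi - lo < 1e-15:
            break
    f = math.exp(0.5 * (lo + hi))
    l = _solve_ligand_given_fe(f, ligand_total, betas, rtol)
    return f, l


def solve_equilibrium(
    comp: MediumComposition,
    tf: TransferrinParameters | None = None,
    chelator: ChelatorDefinition | None = None,
    *,
    protonation_correction: bool = True,
    rtol: float = 1e-10,
    max_iter: int = 200,
) -> SpeciationState:
    """Solve the full speciation equilibrium of a medium composition.

    Parameters
    ----------
    comp : MediumComposition
        Total pools and conditions.
    tf : TransferrinParameters, optional
        Defaults to the standard conditional constants.
    chelator : ChelatorDefinition, optional
        When absent, ``comp.ligand_total`` must be zero.
    protonation_correction : bool
        Apply the ligand side-reaction coefficient at ``comp.ph``
        (default).  Disable to use the tabulated constants as-is.
    rtol : float
        Relative tolerance on every mass balance and mass-action law.

    Returns
    -------
    SpeciationState
        Deterministic for fixed inputs; satisfies all balances to
        ``rtol``.

    Raises
    ------
    ValidationError
        Negative pools or ligand without a chelator definition.
    SolverError
        Non-convergence after the bisection fallback (carries a
        residual report).
    """
    if tf is None:
        tf = TransferrinParameters()
    if chelator is None and comp.ligand_total > 0:
        raise ValidationError(
            "ligand_total > 0 requires a chelator definition"
        )

    if chelator is not None:
        logb = (
            effective_betas(chelator, comp.ph)
            if protonation_correction
            else list(chelator.log_beta)
        )
        betas = [10.0 ** b for b in logb]
    else:
        betas = []

    fe_total = comp.fe_total
    ligand_total = comp.ligand_total if chelator is not None else 0.0
    tf_total = comp.tf_total
    k1, k2 = tf.k1, tf.k2

    # trivial: no iron anywhere
    if fe_total <= CONC_FLOOR:
        return SpeciationState(
            free_fe=0.0,
            free_ligand=ligand_total,
            tf0=tf_total,
            tf1=0.0,
            tf2=0.0,
            complexes=tuple(0.0 for _ in betas),
        )

    if ligand_total <= CONC_FLOOR:
        f = _solve_fe_only(fe_total, tf_total, k1, k2, rtol)
        l = 0.0
    else:
        sol = _newton_2d(
            fe_total, ligand_total, tf_total, k1, k2, betas, rtol, max_iter
        )
        if sol is None:
            sol = _nested_bisection(
                fe_total, ligand_total, tf_total, k1, k2, betas, rtol
            )
            polished = _newton_2d(
                fe_total, ligand_total, tf_total, k1, k2, betas, rtol,
                max_iter, start=sol,
            )
            if polished is not None:
                sol = polished
        f, l = sol

    tf0, tf1, tf2, complexes = _species(f, l, tf_total, k1, k2, betas)
    state = SpeciationState(
        free_fe=f, free_ligand=l, tf0=tf0, tf1=tf1, tf2=tf2, complexes=complexes
    )

    fe_err = abs(state.fe_total - fe_total) / max(fe_total, CONC_FLOOR)
    lig_err = (
        abs(state.ligand_total - ligand_total) / max(ligand_total, CONC_FLOOR)
        if ligand_total > CONC_FLOOR
        else 0.0
    )
    if fe_err > rtol or lig_err > rtol:
        raise SolverError(
            "equilibrium solver did not converge",
            residuals={"iron_rel": fe_err, "ligand_rel": lig_err,
                       "free_fe": f, "free_ligand": l},
        )
    return state


def compute_pfe(
    binder: ChelatorDefinition | TransferrinParameters,
    fe_total: float = 1e-6,
    ligand_total: float = 1e-5,
    ph: float = 7.4,
    *,
    protonation_correction: bool = True,
) -> float:
    """pFe3+ = -log10 [Fe3+] at the reference composition.

    The convention is 1 umol/L total iron and 10 umol/L total ligand at
    pH 7.4.  For transferrin, "ligand" is interpreted as protein
    molecules (10 umol/L protein, hence 20 umol/L iron sites), matching
    the convention of the literature values this figure is compared to.
    Higher pFe means stronger effective binding.
    """
    if isinstance(binder, TransferrinParameters):
        comp = MediumComposition(
            tf_total=ligand_total, fe_total=fe_total, ligand_total=0.0, ph=ph
        )
        state = solve_equilibrium(comp, tf=binder)
    else:
        comp = MediumComposition(
            tf_total=0.0, fe_total=fe_total, ligand_total=ligand_total, ph=ph
        )
        state = solve_equilibrium(
            comp, chelator=binder, protonation_correction=protonation_correction
        )
    return -math.log10(max(state.free_fe, CONC_FLOOR))
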