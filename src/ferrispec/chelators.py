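"""Iron-chelator definitions and protonation (side-reaction) corrections.

A chelator L binds ferric iron through cumulative equilibria

    Fe3+ + i L  <=>  FeL_i        beta_i = [FeL_i] / ([Fe3+][L]^i)

with ``beta_i`` in (L/mol)^i.  Tabulated stability constants refer to the
fully deprotonated ligand.  At physiological pH a large share of the
ligand is protonated and unavailable for metal binding; the standard
side-reaction coefficient

    alpha_L(pH) = [L] / ([L] + [HL] + [H2L] + ...)
                = (1 + 10^(pK_m - pH) + 10^(pK_m + pK_{m-1} - 2 pH) + ...)^-1

converts each beta_i into a conditional constant beta_i' = beta_i *
alpha_L^i valid at that pH.  Deferiprone (pKa 3.68, 9.77) loses roughly
2.4 log units per bound ligand at pH 7.4, which is what makes it a
gentler iron buffer than its thermodynamic constants alone suggest.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import ValidationError

__all__ = [
    "ChelatorDefinition",
    "DEFERIPRONE",
    "BUILTIN_CHELATORS",
    "get_chelator",
    "side_reaction_log_alpha",
    "effective_betas",
]


@dataclass(frozen=True)
class ChelatorDefinition:
    """Stoichiometry and stability constants of an iron(III) chelator.

    Parameters
    ----------
    name : str
        Identifier, e.g. ``"deferiprone"``.
    n_max : int
        Ligands per Fe3+ in the highest complex (3 for a bidentate
        ligand saturating the octahedral coordination sphere).
    log_beta : tuple of float
        log10 of the cumulative stability constants beta_1..beta_n_max
        for the fully deprotonated ligand.
    pka : tuple of float, optional
        Ligand proton-dissociation constants as -log10 Ka, sorted
        ascending.  When present, conditional constants are derived via
        the side-reaction coefficient; when absent the tabulated
        constants are used as-is.
    ligand_molar_mass : float
        Molar mass of the free ligand in g/mol.
    """

    name: str
    n_max: int
    log_beta: tuple[float, ...]
    ligand_molar_mass: float
    pka: tuple[float, ...] | None = None

    def __post_init__(self):
        object.__setattr__(self, "log_beta", tuple(float(b) for b in self.log_beta))
        if self.pka is not None:
            object.__setattr__(self, "pka", tuple(float(p) for p in self.pka))
        if self.n_max < 1:
            raise ValidationError(f"n_max must be >= 1, got {self.n_max}")
        if len(self.log_beta) != self.n_max:
            raise ValidationError(
                f"log_beta must have length n_max={self.n_max}, "
                f"got {len(self.log_beta)}"
            )
        if not self.ligand_molar_mass > 0:
            raise ValidationError("ligand_molar_mass must be positive")
        if self.pka is not None and list(self.pka) != sorted(self.pka):
            raise ValidationError("pka values must be sorted ascending")


def side_reaction_log_alpha(pka: tuple[float, ...], ph: float) -> float:
    """log10 of the free-ligand side-reaction coefficient alpha_L at ``ph``.

    alpha_L is the fraction of uncomplexed ligand present in the fully
    deprotonated, metal-reactive form.  Protons add to the ligand in
    order of decreasing pKa, so the j-fold protonated term carries the
    sum of the j highest pKa values.
    """
    if not 0.0 < ph < 14.0:
        raise ValidationError(f"ph must lie in (0, 14), got {ph}")
    inv_alpha = 1.0
    acc = 0.0
    for j, pk in enumerate(sorted(pka, reverse=True), start=1):
        acc += pk
        inv_alpha += 10.0 ** (acc - j * ph)
    return -math.log10(inv_alpha)


def effective_betas(chelator: ChelatorDefinition, ph: float) -> list[float]:
    """Conditional log10 cumulative stability constants at ``ph``.

    Returns ``log_beta`` unchanged when the chelator carries no pKa
    data; otherwise applies beta_i' = beta_i * alpha_L(pH)^i.
    """
    if not 0.0 < ph < 14.0:
        raise ValidationError(f"ph must lie in (0, 14), got {ph}")
    if chelator.pka is None:
        return list(chelator.log_beta)
    la = side_reaction_log_alpha(chelator.pka, ph)
    return [b + (i + 1) * la for i, b in enumerate(chelator.log_beta)]


DEFERIPRONE = ChelatorDefinition(
    name="deferiprone",
    n_max=3,
    log_beta=(15.01, 27.30, 37.43),
    pka=(3.68, 9.77),
    ligand_molar_mass=139.1,
)

# Stoichiometries of the other chelators used for iron loading
# (deferoxamine 1:1, deferasirox 2:1, hinokitiol 3:1).  Stability
# constants are deliberately not shipped for these; supply log_beta
# explicitly to build a full definition.
_BUILTIN_STOICHIOMETRY: dict[str, tuple[int, float]] = {
    "deferoxamine": (1, 560.6),
    "deferasirox": (2, 373.4),
    "hinokitiol": (3, 164.2),
}

BUILTIN_CHELATORS: dict[str, ChelatorDefinition] = {"deferiprone": DEFERIPRONE}


def get_chelator(
    name: str,
    log_beta: tuple[float, ...] | None = None,
    pka: tuple[float, ...] | None = None,
) -> ChelatorDefinition:
    """Look up a built-in chelator, optionally overriding its constants.

    Only deferiprone ships with stability constants; the other built-in
    names (deferoxamine, deferasirox, hinokitiol) fix stoichiometry and
    molar mass but require user-supplied ``log_beta``.
    """
    key = name.lower()
    if key in BUILTIN_CHELATORS and log_beta is None:
        return BUILTIN_CHELATORS[key]
    if key in BUILTIN_CHELATORS:
        base = BUILTIN_CHELATORS[key]
        return ChelatorDefinition(
            name=key,
            n_max=base.n_max,
            log_beta=tuple(log_beta),
            pka=pka if pka is not None else base.pka,
            ligand_molar_mass=base.ligand_molar_mass,
        )
    if key in _BUILTIN_STOICHIOMETRY:
        n_max, mass = _BUILTIN_STOICHIOMETRY[key]
        if log_beta is None:
            raise ValidationError(
                f"no stability constants are shipped for {name!r}; "
                "pass log_beta explicitly"
            )
        return ChelatorDefinition(
            name=key, n_max=n_max, log_beta=tuple(log_beta), pka=pka,
            ligand_molar_mass=mass,
        )
    raise ValidationError(f"unknown chelator {name!r}")
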