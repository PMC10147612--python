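"""Independent 1-D root-finding oracles for the equilibrium subsystems.

These deliberately avoid the package solver: each reduces a subsystem
to a single scalar equation solved by scipy's brentq, providing a
route that shares no code with the damped-Newton implementation under
test.
"""

import math

from scipy.optimize import brentq

LOG_FLOOR = -45.0


def free_fe_chelator_free(fe_total, tf_total, k1, k2):
    """Free ferric iron for a transferrin-only medium (no chelator)."""

    def res(lf):
        f = 10.0 ** lf
        d = 1.0 + k1 * f + k1 * k2 * f * f
        return f + tf_total * (k1 * f + 2.0 * k1 * k2 * f * f) / d - fe_total

    hi = math.log10(fe_total)
    if res(hi) <= 0:  # transferrin captures nothing
        return fe_total
    return 10.0 ** brentq(res, LOG_FLOOR, hi, xtol=1e-14)


def species_chelator_free(fe_total, tf_total, k1, k2):
    """All species for a transferrin-only medium, via the 1-D oracle."""
    f = free_fe_chelator_free(fe_total, tf_total, k1, k2)
    d = 1.0 + k1 * f + k1 * k2 * f * f
    tf0 = tf_total / d
    tf1 = tf0 * k1 * f
    tf2 = tf1 * k2 * f
    return {"free_fe": f, "tf0": tf0, "tf1": tf1, "tf2": tf2}


def free_ligand_tf_free(fe_total, ligand_total, log_betas):
    """Free ligand for a chelator-only medium (no transferrin).

    For fixed free ligand l, the iron balance gives free iron in closed
    form, f = fe_total / (1 + sum beta_i l^i); substituting into the
    ligand balance leaves one equation in l.
    """
    betas = [10.0 ** b for b in log_betas]

    def res(ll):
        l = 10.0 ** ll
        s = sum(b * l ** (i + 1) for i, b in enumerate(betas))
        f = fe_total / (1.0 + s)
        bound = f * sum((i + 1) * b * l ** (i + 1) for i, b in enumerate(betas))
        return l + bound - ligand_total

    hi = math.log10(ligand_total)
    ll = brentq(res, LOG_FLOOR, hi, xtol=1e-14)
    return 10.0 ** ll


def species_tf_free(fe_total, ligand_total, log_betas):
    """All species for a chelator-only medium, via the 1-D oracle."""
    betas = [10.0 ** b for b in log_betas]
    l = free_ligand_tf_free(fe_total, ligand_total, log_betas)
    s = sum(b * l ** (i + 1) for i, b in enumerate(betas))
    f = fe_total / (1.0 + s)
    complexes = [b * f * l ** (i + 1) for i, b in enumerate(betas)]
    return {"free_fe": f, "free_ligand": l, "complexes": complexes}
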