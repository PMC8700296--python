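import numpy as np
import pytest
from scipy.optimize import root

from agopam import synthetic_data as sd


@pytest.fixture(scope="session")
def geometry():
    """Synthetic shell + ligand geometry with analytic cavity volume."""
    return sd.generate_geometry_fixtures(seed=3)


@pytest.fixture(scope="session")
def shell_cavity_points(geometry):
    """Cavity site points of the hollow shell (computed once; ~1.5 s)."""
    from agopam import structure_volume as sv

    return sv.detect_cavity_points(
        geometry["shell"], (0.0, 0.0, 0.0), focus_radius=6.0, opening=8.0, spacing=0.5
    )


def equilibrium_active_fraction(alpha, k_inact, beta, conc):
    """Independent oracle: numerically solve the four-species mass-action
    equilibrium (R, R*, AR, AR*; ligand in excess) and count active species.

    Unknowns are the four species fractions; the equations are the three
    equilibrium relations plus receptor conservation, solved from a generic
    interior start rather than by the closed form under test.
    """
    c = conc / k_inact  # dimensionless occupancy variable

    def equations(v):
        r, rstar, ar, arstar = v
        # each relation scaled to O(1) so the solver tolerance is meaningful
        return [
            r - alpha * rstar,
            (ar - r * c) / (1.0 + c),
            (arstar - rstar * c * beta) / (1.0 + c * beta),
            r + rstar + ar + arstar - 1.0,
        ]

    sol = root(equations, x0=[0.25, 0.25, 0.25, 0.25], tol=1e-13)
    assert np.max(np.abs(equations(sol.x))) < 1e-11
    r, rstar, ar, arstar = sol.x
    return (rstar + arstar) / (r + rstar + ar + arstar)


@pytest.fixture(scope="session")
def equilibrium_oracle():
    return equilibrium_active_fraction
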