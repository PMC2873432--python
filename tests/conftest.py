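"""Shared fixtures and independent oracles.

The matrix-exponential oracle builds the 6x6 rate matrix by hand, entry by
entry from the narrated transitions, so that it stays independent of the
package's own system-matrix assembly.
"""

import numpy as np
import pytest
from scipy.linalg import expm

from phybdyn.growth import GrowthParameters
from phybdyn.model import RateConstants


@pytest.fixture
def rc() -> RateConstants:
    """Paper-fit rate constants (the package defaults)."""
    return RateConstants()


@pytest.fixture
def gp() -> GrowthParameters:
    """Generator ground-truth growth parameters (agar asymptote 13.29 mm)."""
    return GrowthParameters()


def oracle_matrix(rc: RateConstants, k_1: float, k_2: float,
                  nuclear_photoconversion: bool = True):
    """Hand-built full-model rate matrix, order (Pr_c, Pfr_c, Pr_n, Pfr_n,
    Pr_ns, Pfr_ns); written out transition by transition."""
    A = np.zeros((6, 6))
    # cytosol: photoconversion, reversion, import of Pfr, degradation
    A[0, 0] = -(k_1 + rc.k_dr)
    A[0, 1] = k_2 + rc.k_r
    A[1, 0] = k_1
    A[1, 1] = -(k_2 + rc.k_r + rc.k_in + rc.k_dfr)
    # nucleoplasm: photoconversion (optional), reversion, NB exchange
    kn1 = k_1 if nuclear_photoconversion else 0.0
    kn2 = k_2 if nuclear_photoconversion else 0.0
    A[2, 2] = -(kn1 + rc.k_dr)
    A[2, 3] = kn2 + rc.k_r
    A[2, 4] = rc.k_5
    A[3, 1] = rc.k_in
    A[3, 2] = kn1
    A[3, 3] = -(kn2 + rc.k_r + rc.k_3 + rc.k_dfr)
    A[3, 5] = rc.k_4
    # nuclear bodies: no reversion (protected), Pr decomposition at k_5
    A[4, 4] = -(kn1 + rc.k_5 + rc.k_dr)
    A[4, 5] = kn2
    A[5, 3] = rc.k_3
    A[5, 4] = kn1
    A[5, 5] = -(kn2 + rc.k_4 + rc.k_dfr)
    b = np.zeros(6)
    b[0] = rc.z * rc.k_dr
    return A, b


def expm_solution(A: np.ndarray, b: np.ndarray, x0: np.ndarray,
                  times: np.ndarray) -> np.ndarray:
    """Exact affine-system solution x(t) = x* + e^{At}(x0 - x*)."""
    x_star = np.linalg.solve(A, -b)
    return np.array([x_star + expm(A * t) @ (x0 - x_star) for t in times])
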