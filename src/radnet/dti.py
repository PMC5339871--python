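"""Diffusion-tensor fitting and scalar diffusion metrics.

Multi-direction diffusion-weighted signals (>= 6 non-collinear encoding
directions at a single b-value) determine the six unique components of the
effective self-diffusion tensor through the Stejskal-Tanner relation

    ln(S_i / S_0) = -b * g_i^T D g_i .

From the tensor eigenvalues (lambda1 >= lambda2 >= lambda3) the standard
scalar maps are derived: axial diffusivity AD = lambda1 (diffusion along the
principal direction), radial diffusivity RD = (lambda2 + lambda3) / 2,
mean diffusivity MD = trace / 3, and fractional anisotropy FA, the normalised
dispersion of the eigenvalues in [0, 1] (0 = isotropic, 1 = perfectly
directional).  A region of interest is summarised by its median metric value,
which is what enters the per-sample trait table downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DiffusionTensor",
    "ScalarMetrics",
    "fit_tensor",
    "scalar_metrics",
    "roi_median",
    "read_gradients",
]


@dataclass(frozen=True)
class DiffusionTensor:
    """Symmetric 3x3 diffusion tensor, units mm^2/s."""

    tensor: np.ndarray  # full symmetric 3x3 matrix

    def __post_init__(self) -> None:
        t = np.asarray(self.tensor, dtype=float)
        if t.shape != (3, 3):
            raise ValueError("tensor must be 3x3")
        if not np.allclose(t, t.T, atol=1e-12, rtol=0.0):
            raise ValueError("tensor must be symmetric")
        object.__setattr__(self, "tensor", (t + t.T) / 2.0)

    @property
    def components(self) -> np.ndarray:
        """Unique components (Dxx, Dyy, Dzz, Dxy, Dxz, Dyz)."""
        t = self.tensor
        return np.array([t[0, 0], t[1, 1], t[2, 2], t[0, 1], t[0, 2], t[1, 2]])

    @property
    def eigenvalues(self) -> np.ndarray:
        """Eigenvalues sorted descending (lambda1 >= lambda2 >= lambda3)."""
        return np.linalg.eigvalsh(self.tensor)[::-1]

    @classmethod
    def from_components(cls, dxx, dyy, dzz, dxy, dxz, dyz) -> "DiffusionTensor":
        return cls(np.array([[dxx, dxy, dxz], [dxy, dyy, dyz], [dxz, dyz, dzz]], dtype=float))


@dataclass(frozen=True)
class ScalarMetrics:
    """Scalar diffusion metrics of one tensor.

    ``negative_eigenvalues`` flags physically implausible fits (noise can push
    an eigenvalue below zero); values are reported unclipped.
    """

    AD: float
    RD: float
    MD: float
    FA: float
    eigenvalues: np.ndarray = field(repr=False)
    negative_eigenvalues: bool = False


def _design_matrix(gradients: np.ndarray) -> np.ndarray:
    g = gradients
    # column order matches DiffusionTensor.from_components
    return np.column_stack(
        [
            g[:, 0] ** 2,
            g[:, 1] ** 2,
            g[:, 2] ** 2,
            2.0 * g[:, 0] * g[:, 1],
            2.0 * g[:, 0] * g[:, 2],
            2.0 * g[:, 1] * g[:, 2],
        ]
    )


def fit_tensor(b0_signal: float, signals, gradients, b_value: float) -> DiffusionTensor:
    """Ordinary log-linear least-squares fit of the diffusion tensor.

    Parameters
    ----------
    b0_signal:
        Signal without diffusion weighting (S_0 > 0).
    signals:
        Diffusion-weighted signals, one per gradient direction, all > 0.
    gradients:
        Unit 3-vectors of the encoding directions; at least 6 non-collinear
        directions are required for the system to be determined.
    b_value:
        Diffusion weighting in s/mm^2.

    Exact in the noiseless case: forward-simulated signals recover the
    generating tensor to machine precision.
    """
    signals = np.asarray(signals, dtype=float)
    gradients = np.asarray(gradients, dtype=float)
    if gradients.ndim != 2 or gradients.shape[1] != 3:
        raise ValueError("gradients must be an (n, 3) array of unit vectors")
    if signals.shape[0] != gradients.shape[0]:
        raise ValueError("signals and gradients must have equal length")
    if gradients.shape[0] < 6:
        raise ValueError(
            f"tensor fit needs >= 6 gradient directions, got {gradients.shape[0]}: "
            "the six tensor components are underdetermined"
        )
    if b0_signal <= 0 or np.any(signals <= 0):
        raise ValueError("all signals (including b0) must be positive")
    norms = np.linalg.norm(gradients, axis=1)
    if np.any(np.abs(norms - 1.0) > 1e-6):
        raise ValueError("gradient directions must be unit vectors")

    design = _design_matrix(gradients)
    if np.linalg.matrix_rank(design) < 6:
        raise ValueError(
            "gradient design matrix is rank-deficient (collinear directions); "
            "the six tensor components cannot be resolved"
        )
    y = -np.log(signals / b0_signal) / float(b_value)
    comps, *_ = np.linalg.lstsq(design, y, rcond=None)
    return DiffusionTensor.from_components(*comps)


def scalar_metrics(tensor: DiffusionTensor) -> ScalarMetrics:
    """AD, RD, MD and FA from a fitted tensor.

    FA = sqrt(3/2) * sqrt(sum_i (lambda_i - MD)^2) / sqrt(sum_i lambda_i^2),
    defined as 0 for the all-zero tensor. Negative eigenvalues (possible in
    noisy fits) are not clipped; the result carries a flag instead, so that
    downstream QC can exclude the voxel rather than receive a silently biased
    FA.
    """
    lam = tensor.eigenvalues
    if not np.all(np.isfinite(lam)):
        raise ValueError("tensor eigenvalues are not finite")
    md = float(lam.mean())
    ad = float(lam[0])
    rd = float((lam[1] + lam[2]) / 2.0)
    denom = float(np.sum(lam**2))
    if denom == 0.0:
        fa = 0.0
    else:
        fa = float(np.sqrt(1.5) * np.sqrt(np.sum((lam - md) ** 2)) / np.sqrt(denom))
    return ScalarMetrics(
        AD=ad,
        RD=rd,
        MD=md,
        FA=fa,
        eigenvalues=lam,
        negative_eigenvalues=bool(np.any(lam < 0)),
    )


def roi_median(values, mask=None) -> float:
    """Median of the masked values — the per-sample ROI summary statistic.

    Even counts use the midpoint of the two central order statistics.
    """
    values = np.asarray(values, dtype=float)
    if mask is None:
        mask = np.ones(values.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != values.shape:
        raise ValueError("mask and values must have identical shape")
    selected = values[mask]
    if selected.size == 0:
        raise ValueError("ROI mask selects no voxels")
    return float(np.median(selected))


def read_gradients(path) -> np.ndarray:
    """Read a plain-text gradient table, one unit 3-vector per row."""
    g = np.loadtxt(path, ndmin=2)
    if g.shape[1] != 3:
        raise ValueError(f"gradient table must have 3 columns, got {g.shape[1]}")
    return g
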