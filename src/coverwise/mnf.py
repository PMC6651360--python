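"""Spectral smoothing and the Minimum Noise Fraction transform.

The MNF transform is a noise-whitened principal component rotation: it
solves the generalized symmetric eigenproblem

    Sigma_total v = lambda Sigma_noise v,

orders components by decreasing eigenvalue (a signal-to-noise ordering) and
projects mean-centred pixel spectra onto the eigenvectors.  With an
isotropic noise covariance it reduces to ordinary PCA.  The noise covariance
is estimated from horizontal shift differences, the standard practice when
no dark-current measurements are available.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import linalg, signal

from .scene import ConfigurationError, HyperCube


class ParameterError(ValueError):
    pass


def savitzky_golay_smooth(cube: HyperCube, window: int = 13,
                          polyorder: int = 2) -> HyperCube:
    """Savitzky-Golay smoothing of every pixel spectrum along the band axis.

    Each band value is replaced by the value of the local least-squares
    polynomial of degree ``polyorder`` fitted over ``window`` bands; at the
    spectrum edges the polynomial fitted to the first/last full window is
    evaluated (scipy's ``mode='interp'``).
    """
    if window % 2 == 0 or window <= polyorder:
        raise ParameterError("window must be odd and greater than polyorder")
    if window > cube.n_bands:
        raise ParameterError("window exceeds the number of bands")
    data = signal.savgol_filter(cube.data, window_length=window,
                                polyorder=polyorder, axis=0, mode="interp")
    return HyperCube(data=data, wavelengths=cube.wavelengths,
                     gsd=cube.gsd, transform=cube.transform,
                     nodata_mask=cube.nodata_mask.copy())


def estimate_noise_covariance(cube: HyperCube) -> np.ndarray:
    """Shift-difference noise covariance estimate.

    For horizontally adjacent valid pixels, d = r(p) - r(p_right) is
    dominated by noise wherever the signal is spatially smooth; since d is
    the difference of two i.i.d. noise draws, cov(d)/2 estimates the noise
    covariance.  Symmetric PSD by construction.
    """
    valid = ~cube.nodata_mask
    pair = valid[:, :-1] & valid[:, 1:]
    if not np.any(pair):
        raise ParameterError("need at least one valid horizontal pixel pair")
    diffs = (cube.data[:, :, :-1] - cube.data[:, :, 1:])[:, pair].T
    if diffs.shape[0] < cube.n_bands + 1:
        warnings.warn(
            f"only {diffs.shape[0]} difference samples for {cube.n_bands} "
            "bands; noise covariance estimate will be ill-conditioned",
            RuntimeWarning)
    diffs = diffs - diffs.mean(axis=0)
    denom = max(diffs.shape[0] - 1, 1)
    return (diffs.T @ diffs) / denom / 2.0


@dataclass
class MNFResult:
    """Forward MNF rotation and the transformed cube.

    ``forward_transform`` columns are the generalized eigenvectors scaled so
    that V.T @ noise_cov @ V = I; ``eigenvalues`` are the corresponding
    total-to-noise variance ratios in nonincreasing order.
    """

    forward_transform: np.ndarray      # (B, B), columns = eigenvectors
    eigenvalues: np.ndarray            # (B,), nonincreasing
    components: HyperCube              # transformed bands, eigenvalue order
    noise_cov: np.ndarray              # (B, B) as used (after regularization)
    signal_cov: np.ndarray             # (B, B) total sample covariance
    mean: np.ndarray                   # (B,) band means of valid pixels

    def backtransform(self, k: int | None = None) -> np.ndarray:
        """Reconstruct mean-centred spectra (B, R, C) from the first k components."""
        B = self.forward_transform.shape[0]
        k = B if k is None else k
        inv = np.linalg.inv(self.forward_transform.T)   # (B, B)
        comp = self.components.data[:k]
        return np.einsum("bk,krc->brc", inv[:, :k], comp)


def _regularize(noise_cov: np.ndarray, eps_scale: float = 1e-8) -> np.ndarray:
    noise_cov = 0.5 * (noise_cov + noise_cov.T)
    B = noise_cov.shape[0]
    eps = eps_scale * max(np.trace(noise_cov), 1.0) / B
    try:
        linalg.cholesky(noise_cov, lower=True)
        return noise_cov
    except linalg.LinAlgError:
        pass
    reg = noise_cov + eps * np.eye(B)
    try:
        linalg.cholesky(reg, lower=True)
    except linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "noise covariance singular even after regularization") from exc
    return reg


def mnf_transform(cube: HyperCube, noise_cov: np.ndarray | None = None) -> MNFResult:
    """Minimum Noise Fraction rotation of a cube.

    Components are ordered by decreasing eigenvalue of the generalized
    problem (total vs noise covariance); each eigenvector is scaled so its
    largest-magnitude loading is positive, making outputs reproducible
    across eigensolvers.
    """
    if noise_cov is None:
        noise_cov = estimate_noise_covariance(cube)
    noise_cov = _regularize(np.asarray(noise_cov, dtype=float))

    X = cube.valid_pixels().astype(float)          # (n, B)
    if X.shape[0] < 2:
        raise ParameterError("need at least two valid pixels")
    mean = X.mean(axis=0)
    Xc = X - mean
    total_cov = (Xc.T @ Xc) / (Xc.shape[0] - 1)

    evals, evecs = linalg.eigh(total_cov, noise_cov)   # ascending
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    # sign convention: largest-|loading| entry positive
    flip = np.sign(evecs[np.argmax(np.abs(evecs), axis=0),
                         np.arange(evecs.shape[1])])
    flip[flip == 0] = 1.0
    evecs = evecs * flip

    B, R, C = cube.data.shape
    comp = np.full((B, R, C), 0.0)
    valid = ~cube.nodata_mask
    comp[:, valid] = (Xc @ evecs).T
    comp_cube = HyperCube(data=comp, wavelengths=np.arange(1, B + 1, dtype=float),
                          gsd=cube.gsd, transform=cube.transform,
                          nodata_mask=cube.nodata_mask.copy())
    return MNFResult(forward_transform=evecs, eigenvalues=evals,
                     components=comp_cube, noise_cov=noise_cov,
                     signal_cov=total_cov, mean=mean)


def select_components(result: MNFResult, k: int = 30) -> HyperCube:
    """First ``k`` MNF components as a k-band cube (most informative first)."""
    B = result.components.n_bands
    if not 1 <= k <= B:
        raise ParameterError(f"k must be in [1, {B}], got {k}")
    return HyperCube(data=result.components.data[:k],
                     wavelengths=result.components.wavelengths[:k],
                     gsd=result.components.gsd,
                     transform=result.components.transform,
                     nodata_mask=result.components.nodata_mask.copy())


def eigenvalues_to_csv(result: MNFResult, path) -> None:
    import pandas as pd

    pd.DataFrame({"component": np.arange(1, result.eigenvalues.size + 1),
                  "eigenvalue": result.eigenvalues}).to_csv(path, index=False)
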