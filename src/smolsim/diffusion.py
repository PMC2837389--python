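"""Per-step stochastic displacement of molecules.

Free molecules take independent Gaussian steps along each coordinate with
per-axis standard deviation sigma = sqrt(2 D dt), optionally plus a
deterministic drift offset or an anisotropic step drawn from a covariance
2 * tensor * dt.  Surface-bound molecules take the same full-dimensional
Gaussian step and are then re-deposited onto their panel along the local
normal; on planar panels the resulting in-plane displacement is exactly
Gaussian (orthogonal projections of Gaussians are Gaussian), while on curved
panels the method requires the radius of curvature to be much larger than the
rms step length.

Units follow the package convention: um, s, um^2/s.
"""

from __future__ import annotations

import numpy as np


class DiffusionStepParams:
    """Pre-computed per-(species, state) step parameters.

    Parameters
    ----------
    n_species, n_states : table dimensions.
    dt : time step.

    Attributes
    ----------
    sigma : (n_species, n_states) rms per-axis displacement sqrt(2 D dt).
    drift : (n_species, 3) drift offset per step (drift velocity * dt),
        applied to solution-state molecules.
    chol : dict species -> (3, 3) Cholesky factor of ``2 * tensor * dt`` for
        anisotropic diffusers (overrides sigma for the solution state).
    """

    def __init__(self, n_species: int, n_states: int, dt: float, dim: int = 3):
        if dt <= 0:
            raise ValueError("dt must be positive")
        self.dt = float(dt)
        self.dim = dim
        self.diff_coef = np.zeros((n_species, n_states))
        self.sigma = np.zeros((n_species, n_states))
        self.drift = np.zeros((n_species, 3))
        self.chol: dict[int, np.ndarray] = {}

    def set_diff_coef(self, species: int, state: int, D: float):
        if D < 0:
            raise ValueError("diffusion coefficient must be >= 0")
        self.diff_coef[species, state] = D
        self.sigma[species, state] = np.sqrt(2.0 * D * self.dt)

    def set_drift(self, species: int, v) -> None:
        v = np.asarray(v, dtype=float)
        self.drift[species, : v.size] = v * self.dt

    def set_tensor(self, species: int, tensor) -> None:
        """Anisotropic diffusion tensor (symmetric PSD, um^2/s)."""
        t = np.asarray(tensor, dtype=float).reshape(3, 3)
        if not np.allclose(t, t.T, atol=1e-12):
            raise ValueError("diffusion tensor must be symmetric")
        w, v = np.linalg.eigh(t)
        if w.min() < -1e-12 * max(1.0, abs(w).max()):
            raise ValueError("diffusion tensor must be positive semi-definite")
        w = np.clip(w, 0.0, None)
        # Cholesky-like factor valid for PSD (not just PD) tensors
        self.chol[species] = v * np.sqrt(2.0 * w * self.dt)


def diffuse_solution(pos, species, params: DiffusionStepParams, rng,
                     state_col=0, buf=None):
    """Gaussian step (+ drift) for solution-phase molecules, in place.

    ``pos`` is ``(n, 3)``; ``species`` the per-molecule species index.
    Boundary and surface processing is *not* done here; the caller owns the
    old positions and runs crossing detection afterwards.  ``buf`` is an
    optional reusable ``(n, 3)`` scratch array for the normal draws.
    """
    n = len(pos)
    if n == 0:
        return pos
    sigma = params.sigma[species, state_col]
    moving = sigma > 0
    if moving.all():
        if buf is not None:
            rng.standard_normal(out=buf)
            steps = buf
        else:
            steps = rng.standard_normal((n, 3))
        if params.dim < 3:
            steps[:, params.dim:] = 0.0
        smin, smax = sigma.min(), sigma.max()
        if smin == smax:  # single effective species: scalar scale
            steps *= smin
        else:
            steps *= sigma[:, None]
        pos += steps
    elif moving.any():
        steps = rng.standard_normal((int(moving.sum()), 3))
        if params.dim < 3:
            steps[:, params.dim:] = 0.0
        pos[moving] += steps * sigma[moving, None]
    for sp, ch in params.chol.items():
        m = species == sp
        if m.any():
            raw = rng.standard_normal((int(m.sum()), 3))
            disp = raw @ ch.T
            if params.dim < 3:
                disp[:, params.dim:] = 0.0
            # tensor overrides the isotropic step: undo the isotropic draw
            if params.sigma[sp, state_col] > 0:
                pos[m] -= 0.0  # isotropic sigma is zeroed at parse time for difm species
            pos[m] += disp
    drifting = np.abs(params.drift[species]).sum(axis=1) > 0
    if drifting.any():
        pos[drifting] += params.drift[species[drifting]]
    return pos


def diffuse_surface_bound(pos, species, state, panel_of, panels, params, rng):
    """Full-dimensional Gaussian step then re-deposition onto the panel.

    Molecules whose orthogonal projection leaves their finite panel are moved
    to the nearest point of any panel of the same surface (the caller passes a
    ``reattach`` list per panel); here we clamp to the own panel and return
    the mask of molecules that were clamped so the caller can reattach.
    """
    n = len(pos)
    if n == 0:
        return pos
    sigma = params.sigma[species, state]
    moving = sigma > 0
    if not moving.any():
        return pos
    idx = np.flatnonzero(moving)
    steps = rng.standard_normal((len(idx), 3))
    if params.dim < 3:
        steps[:, params.dim:] = 0.0
    raw = pos[idx] + steps * sigma[idx, None]
    for pid in np.unique(panel_of[idx]):
        m = panel_of[idx] == pid
        pos[idx[m]] = panels[pid].project(raw[m])
    return pos


def apply_anisotropic(pos, chol, rng, dim=3):
    """Displace positions with a zero-mean multivariate normal of covariance
    ``2 * tensor * dt`` (``chol`` is the precomputed factor)."""
    raw = rng.standard_normal((len(pos), 3))
    disp = raw @ chol.T
    if dim < 3:
        disp[:, dim:] = 0.0
    return pos + disp
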