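"""Small-grid 3D-RISM solver with the Kovalenko-Hirata closure.

The solver computes solvent-site distribution functions g_g(r) around a
rigid solute on a regular 3-D grid by iterating the 3D Ornstein-Zernike
relation (a convolution with the pure-solvent site-site susceptibility,
evaluated by FFT) together with the KH closure

    d = -beta u + h - c,   g = exp(d) if d <= 0 else 1 + d,

which guarantees g >= 0 and admits a closed-form excess chemical potential
(:func:`kh_free_energy`) used to cross-validate the charging integral.

Long-range electrostatics is handled by a Gaussian split: the solute
potential is divided into erf/erfc parts with width ``eta``; the erf part is
carried analytically in reciprocal space (with the k = 0 term removed,
i.e. a neutralising background), so all FFT-transformed quantities are
short-ranged.  Writing c = c_s - beta*u_long, both the closure argument and
the closure output reduce to short-range combinations:

    d = -beta u_s + t_s,   c_s_new = g - 1 - t_s,   t_s = h - c_s,

with the long-range term entering only the reciprocal-space OZ product.

The solvent input is a site-site susceptibility chi(k).  The default is the
analytic dilute ("rigid molecule") susceptibility chi = omega; a dressed
chi = omega + rho*h from the 1-D site-site RISM solver, or one loaded from a
text file, can be substituted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.fft import rfftn, irfftn, fftfreq, rfftfreq, dst
from scipy.special import erfc

from .constants import K_E
from .solvation_core import (
    DistributionFields,
    SolventModel,
    SolventSite,
    ThermodynamicState,
    _lj_softcore,
    _lj_term,
    _mix,
)

__all__ = [
    "Grid3D",
    "SolventSusceptibility",
    "RismSolution",
    "RismConvergenceError",
    "BoxTooSmallError",
    "analytic_susceptibility",
    "solve_1d_rism",
    "solve_3d_rism",
    "kh_free_energy",
    "rism_provider",
    "RismProvider",
    "write_susceptibility",
    "read_susceptibility",
    "write_volumetric",
]

#: Width of the Gaussian charge split (A).
DEFAULT_ETA = 1.0


class RismConvergenceError(RuntimeError):
    def __init__(self, message: str, residuals=None):
        super().__init__(message)
        self.residuals = list(residuals or [])


class BoxTooSmallError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# Grid
# ---------------------------------------------------------------------------

@dataclass
class Grid3D:
    shape: tuple[int, int, int]
    spacing: float
    origin: np.ndarray

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError("grid spacing must be positive")
        self.origin = np.asarray(self.origin, dtype=float)
        self._points = None

    @classmethod
    def around_solute(cls, solute, spacing: float = 0.5,
                      padding: float = 12.0, shape=None) -> "Grid3D":
        """Cubic-cell grid enclosing the solute with the given padding, or
        with an explicit ``shape`` centred on the solute."""
        pos = np.array([s.position for s in solute])
        center = 0.5 * (pos.min(axis=0) + pos.max(axis=0))
        if shape is None:
            extent = (pos.max(axis=0) - pos.min(axis=0)) + 2.0 * padding
            n = [int(np.ceil(e / spacing)) for e in extent]
            shape = tuple(ni + ni % 2 for ni in n)  # even sizes
        origin = center - (np.array(shape) - 1) * spacing / 2.0
        return cls(shape=tuple(shape), spacing=spacing, origin=origin)

    @property
    def n_points(self) -> int:
        return int(np.prod(self.shape))

    @property
    def cell_volume(self) -> float:
        return self.spacing ** 3

    def axes(self) -> list[np.ndarray]:
        return [self.origin[d] + np.arange(self.shape[d]) * self.spacing
                for d in range(3)]

    def points(self) -> np.ndarray:
        """Flattened (N, 3) grid point coordinates (cached)."""
        if self._points is None:
            mesh = np.meshgrid(*self.axes(), indexing="ij")
            self._points = np.stack([m.ravel() for m in mesh], axis=1)
        return self._points

    def k_vectors(self, half: bool = False) -> tuple[np.ndarray, np.ndarray]:
        """(kx, ky, kz) mesh components and |k| on the FFT lattice (the
        Hermitian half-lattice of rfftn when ``half``)."""
        ks = [2.0 * np.pi * fftfreq(n, d=self.spacing) for n in self.shape]
        if half:
            ks[2] = 2.0 * np.pi * rfftfreq(self.shape[2], d=self.spacing)
        mesh = np.meshgrid(*ks, indexing="ij")
        kmag = np.sqrt(mesh[0] ** 2 + mesh[1] ** 2 + mesh[2] ** 2)
        return mesh, kmag

    def boundary_mask(self) -> np.ndarray:
        m = np.zeros(self.shape, dtype=bool)
        m[0, :, :] = m[-1, :, :] = True
        m[:, 0, :] = m[:, -1, :] = True
        m[:, :, 0] = m[:, :, -1] = True
        return m

    def min_padding(self, solute) -> float:
        pos = np.array([s.position for s in solute])
        lo = pos.min(axis=0) - self.origin
        hi = (self.origin + (np.array(self.shape) - 1) * self.spacing
              - pos.max(axis=0))
        return float(min(lo.min(), hi.min()))


# ---------------------------------------------------------------------------
# Solvent susceptibility
# ---------------------------------------------------------------------------

@dataclass
class SolventSusceptibility:
    """Site-site susceptibility chi_ab(k) on a radial k-grid.

    Used in the 3D-OZ product as h_b(k) = sum_a c_a(k) chi_ab(k); the
    dressed form is chi_ab = omega_ab + rho_a h_ab.  ``sites`` carries the
    full solvent-site parameters so the 3-D solver can build potentials.
    """

    sites: list[SolventSite]
    k_grid: np.ndarray
    chi: np.ndarray  # (n_k, n_sites, n_sites)
    provenance: str = "analytic-rigid"

    def __post_init__(self) -> None:
        if not np.allclose(self.chi, np.swapaxes(self.chi, 1, 2),
                           atol=1e-8):
            raise ValueError("susceptibility must be symmetric in sites")

    @property
    def site_names(self) -> list[str]:
        return [s.name for s in self.sites]

    def interp(self, kmag: np.ndarray) -> np.ndarray:
        """chi evaluated at arbitrary |k| (shape kmag.shape + (n, n))."""
        n = len(self.sites)
        out = np.empty(kmag.shape + (n, n))
        for i in range(n):
            for j in range(n):
                out[..., i, j] = np.interp(kmag, self.k_grid,
                                           self.chi[:, i, j])
        return out


def _intramolecular_omega(solvent: SolventModel, k: np.ndarray) -> np.ndarray:
    n = len(solvent.sites)
    omega = np.zeros((len(k), n, n))
    for i in range(n):
        omega[:, i, i] = 1.0
        for j in range(i + 1, n):
            d = solvent.bond_distance(solvent.sites[i].name,
                                      solvent.sites[j].name)
            if d is None:
                continue
            kd = k * d
            w = np.ones_like(kd)
            nz = kd > 1e-12
            w[nz] = np.sin(kd[nz]) / kd[nz]
            omega[:, i, j] = omega[:, j, i] = w
    return omega


def analytic_susceptibility(
    solvent: SolventModel,
    state: ThermodynamicState | None = None,
    k_max: float = 40.0,
    n_k: int = 2000,
) -> SolventSusceptibility:
    """Dilute-solvent susceptibility chi = omega: the intramolecular
    correlation of the rigid molecule (sin(kd)/(kd) between bonded sites,
    identity on the diagonal), with no density dressing.  Analytic and
    self-contained."""
    k = np.linspace(0.0, k_max, n_k)
    return SolventSusceptibility(
        sites=list(solvent.sites), k_grid=k,
        chi=_intramolecular_omega(solvent, k),
        provenance="analytic-rigid",
    )


# ---------------------------------------------------------------------------
# 1-D site-site RISM (optional dressed susceptibility)
# ---------------------------------------------------------------------------

def _radial_ft(f: np.ndarray, r: np.ndarray, dr: float) -> np.ndarray:
    """f(r) -> f(k) = (4 pi / k) int r f sin(kr) dr on the DST-I lattice."""
    n = len(r)
    k = np.pi * np.arange(1, n + 1) / ((n + 1) * dr)
    half = dst(r * f, type=1) / 2.0  # sum_j (r f)_j sin(pi j m / (n+1))
    return (4.0 * np.pi * dr / k) * half


def _radial_ift(F: np.ndarray, r: np.ndarray, dr: float) -> np.ndarray:
    n = len(r)
    k = np.pi * np.arange(1, n + 1) / ((n + 1) * dr)
    dk = np.pi / ((n + 1) * dr)
    half = dst(k * F, type=1) / 2.0
    return (dk / (2.0 * np.pi ** 2 * r)) * half


def solve_1d_rism(
    solvent: SolventModel,
    state: ThermodynamicState | None = None,
    closure: str = "kh",
    n_r: int = 2048,
    dr: float = 0.02,
    eta: float = DEFAULT_ETA,
    tol: float = 1e-6,
    max_iter: int = 20000,
    damping: float = 0.2,
) -> SolventSusceptibility:
    """Site-site Ornstein-Zernike + closure for the pure solvent, returning
    the dressed susceptibility chi = omega + rho h.

    Picard iteration with damping on the short-range direct correlation;
    long-range Coulomb renormalised by the Gaussian split.  ``closure`` is
    "kh" or "hnc".
    """
    state = state or ThermodynamicState()
    beta = state.beta
    sites = solvent.sites
    n = len(sites)
    if len({s.density for s in sites}) > 1:
        raise ValueError(
            "the 1-D dressing assumes a one-component solvent with uniform "
            "site densities; mixtures keep the analytic susceptibility")
    r = (np.arange(1, n_r + 1)) * dr
    k = np.pi * np.arange(1, n_r + 1) / ((n_r + 1) * dr)

    rho = np.array([s.density for s in sites])
    omega_k = _intramolecular_omega(solvent, k)  # (n_k, n, n)

    # pair potentials, short-range parts and analytic long-range transforms
    u_s = np.zeros((n, n, n_r))
    phi_lr_k = 4.0 * np.pi * K_E * np.exp(-(k * eta) ** 2 / 4.0) / k ** 2
    qq = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            sigma, eps = _mix(sites[i].sigma, sites[i].epsilon,
                              sites[j].sigma, sites[j].epsilon)
            u_lj, _ = _lj_softcore(r, sigma, eps, 1.0)
            qq[i, j] = sites[i].charge * sites[j].charge
            u_s[i, j] = u_lj + qq[i, j] * K_E * erfc(r / eta) / r

    c_s = np.zeros((n, n, n_r))
    residuals = []
    for it in range(max_iter):
        c_k = np.empty((n_r, n, n))
        for i in range(n):
            for j in range(n):
                c_k[:, i, j] = _radial_ft(c_s[i, j], r, dr) \
                    - beta * qq[i, j] * phi_lr_k
        # H = (I - Omega C rho)^-1 Omega C Omega, solved per k
        oc = omega_k @ c_k
        a = np.eye(n)[None, :, :] - oc * rho[None, None, :]
        h_k = np.linalg.solve(a, oc @ omega_k)
        t_s_k = np.empty_like(c_k)
        for i in range(n):
            for j in range(n):
                t_s_k[:, i, j] = h_k[:, i, j] - (
                    c_k[:, i, j] + beta * qq[i, j] * phi_lr_k)
        t_s = np.empty_like(c_s)
        for i in range(n):
            for j in range(n):
                t_s[i, j] = _radial_ift(t_s_k[:, i, j], r, dr)
        d = -beta * u_s + t_s
        if closure == "kh":
            g = np.where(d <= 0, np.exp(np.minimum(d, 0)), 1.0 + d)
        elif closure == "hnc":
            g = np.exp(np.minimum(d, 50.0))
        else:
            raise ValueError(f"unknown closure {closure!r}")
        c_new = g - 1.0 - t_s
        res = float(np.sqrt(np.mean((c_new - c_s) ** 2)))
        residuals.append(res)
        c_s = c_s + damping * (c_new - c_s)
        if res < tol:
            break
    else:
        raise RismConvergenceError(
            f"1D-RISM did not converge in {max_iter} iterations "
            f"(residual {residuals[-1]:.2e})", residuals)

    # dressed susceptibility on the k-lattice: chi = omega + rho_a h_ab
    chi = np.empty((n_r, n, n))
    for i in range(n):
        for j in range(n):
            chi[:, i, j] = omega_k[:, i, j] + np.sqrt(rho[i] * rho[j]) \
                * h_k[:, i, j]
    # prepend k=0 row by extrapolation so interp covers small k
    k_full = np.concatenate([[0.0], k])
    chi_full = np.concatenate([chi[:1], chi], axis=0)
    out = SolventSusceptibility(sites=list(sites), k_grid=k_full,
                                chi=chi_full, provenance="1D-RISM")
    out.details = {"r": r, "g": g, "residuals": residuals,
                   "closure": closure}
    return out


# ---------------------------------------------------------------------------
# 3-D solver
# ---------------------------------------------------------------------------

@dataclass
class RismSolution:
    grid: Grid3D
    sites: list[SolventSite]
    g: dict  # name -> flat (N,) array
    h: dict
    c_s: dict
    u_s: dict
    lam_point: tuple[float, float]
    residual: float
    n_iter: int
    converged: bool
    solute: list = field(default_factory=list)
    eta: float = DEFAULT_ETA
    metadata: dict = field(default_factory=dict)

    def c_full(self, state: ThermodynamicState) -> dict:
        """Real-space direct correlation including the long-range Coulomb
        tail (erf-split, bare sum over solute atoms)."""
        from scipy.special import erf

        points = self.grid.points()
        phi = np.zeros(len(points))
        for s in self.solute:
            rr = np.maximum(
                np.linalg.norm(points - s.position, axis=1), 1e-10)
            phi += s.charge * K_E * erf(rr / self.eta) / rr
        lam2 = self.lam_point[1]
        return {sv.name: self.c_s[sv.name]
                - state.beta * lam2 * sv.charge * phi
                for sv in self.sites}


class _Mdiis:
    """Minimal MDIIS accelerator with Picard fallback."""

    def __init__(self, depth: int = 10, damping: float = 0.3):
        self.depth = depth
        self.damping = damping
        self.xs: list[np.ndarray] = []
        self.rs: list[np.ndarray] = []

    def step(self, x: np.ndarray, r: np.ndarray) -> np.ndarray:
        self.xs.append(x)
        self.rs.append(r)
        if len(self.xs) > self.depth:
            self.xs.pop(0)
            self.rs.pop(0)
        m = len(self.xs)
        if m == 1:
            return x + self.damping * r
        b = np.empty((m + 1, m + 1))
        b[:m, :m] = np.array([[float(ri @ rj) for rj in self.rs]
                              for ri in self.rs])
        b[m, :], b[:, m] = 1.0, 1.0
        b[m, m] = 0.0
        rhs = np.zeros(m + 1)
        rhs[m] = 1.0
        try:
            coef = np.linalg.solve(b, rhs)[:m]
        except np.linalg.LinAlgError:
            self.xs, self.rs = [self.xs[-1]], [self.rs[-1]]
            return x + self.damping * r
        x_new = np.zeros_like(x)
        for a, xi, ri in zip(coef, self.xs, self.rs):
            x_new += a * (xi + self.damping * ri)
        return x_new

    def reset(self) -> None:
        self.xs, self.rs = [], []


def _solute_fields(solute, sites, grid: Grid3D, lam_point, beta, eta):
    """Short-range potentials u_s per solvent site and the analytic
    reciprocal-space long-range potential phi_lr(k)."""
    lam1, lam2 = lam_point
    points = grid.points()
    n_pts = len(points)
    # short-range: soft-core LJ + erfc-screened Coulomb
    u_s = {sv.name: np.zeros(n_pts) for sv in sites}
    for s in solute:
        rr = np.maximum(np.linalg.norm(points - s.position, axis=1), 1e-10)
        coul_sr = K_E * s.charge * erfc(rr / eta) / rr
        for sv in sites:
            sigma, eps = _mix(s.sigma, s.epsilon, sv.sigma, sv.epsilon)
            u_lj, _ = _lj_term(rr, sigma, eps, lam_point)
            u_s[sv.name] += u_lj + lam2 * sv.charge * coul_sr
    # reciprocal-space long-range solute potential (k=0 removed)
    kmesh, kmag = grid.k_vectors(half=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        k2 = kmag ** 2
        env = 4.0 * np.pi * K_E * np.exp(-k2 * eta ** 2 / 4.0) / k2
    env[kmag == 0] = 0.0
    structure = np.zeros(kmag.shape, dtype=complex)
    for s in solute:
        dr_vec = s.position - grid.origin
        phase = (kmesh[0] * dr_vec[0] + kmesh[1] * dr_vec[1]
                 + kmesh[2] * dr_vec[2])
        structure += s.charge * np.exp(-1j * phase)
    phi_lr_k = env * structure  # continuous-FT convention relative to origin
    return u_s, phi_lr_k, kmag


def solve_3d_rism(
    solute,
    susceptibility: SolventSusceptibility,
    grid: Grid3D,
    state: ThermodynamicState | None = None,
    lam_point: tuple[float, float] = (1.0, 1.0),
    closure: str = "kh",
    tol: float = 1e-5,
    max_iter: int = 10000,
    mdiis_depth: int = 10,
    damping: float = 0.3,
    eta: float = DEFAULT_ETA,
    warm_start: dict | None = None,
    boundary_tol: float | None = None,
    min_padding: float = 0.0,
) -> RismSolution:
    """Solve the 3D-RISM/KH equations for a rigid solute.

    Iterates the OZ convolution (FFT) and the KH closure on the short-range
    direct correlation with MDIIS acceleration, to an RMS residual below
    ``tol``.  ``lam_point`` scales the solute potential per the charging
    path; ``warm_start`` may carry the c_s dict of a previous (nearby)
    lambda node.  If ``boundary_tol`` is set, a converged solution whose
    |h| on the box boundary exceeds it raises :class:`BoxTooSmallError`.
    """
    if closure != "kh":
        raise ValueError("the 3-D solver supports the KH closure only")
    state = state or ThermodynamicState()
    beta = state.beta
    sites = susceptibility.sites
    names = [sv.name for sv in sites]

    if min_padding and grid.min_padding(solute) < min_padding:
        raise BoxTooSmallError(
            f"grid padding {grid.min_padding(solute):.1f} A below required "
            f"{min_padding:.1f} A")

    lam1, lam2 = lam_point
    if lam1 == 0.0 and lam2 == 0.0:
        n_pts = grid.n_points
        zero = {nm: np.zeros(n_pts) for nm in names}
        return RismSolution(
            grid=grid, sites=sites,
            g={nm: np.ones(n_pts) for nm in names},
            h=dict(zero), c_s={nm: np.zeros(n_pts) for nm in names},
            u_s={nm: np.zeros(n_pts) for nm in names},
            lam_point=lam_point, residual=0.0, n_iter=0, converged=True,
            solute=list(solute), eta=eta,
            metadata={"closure": closure, "note": "zero coupling"},
        )

    u_s, phi_lr_k, kmag = _solute_fields(solute, sites, grid, lam_point,
                                         beta, eta)
    chi_k = susceptibility.interp(kmag)  # shape + (n, n)
    minus_beta_us = {nm: -beta * u_s[nm] for nm in names}
    c_long_k = [-beta * lam2 * sv.charge * phi_lr_k for sv in sites]

    shape = grid.shape
    dV = grid.cell_volume
    n = len(sites)

    if warm_start is not None:
        c_s = [np.array(warm_start[nm], dtype=float).reshape(shape)
               for nm in names]
    else:
        c_s = [np.zeros(shape) for _ in names]

    mdiis = _Mdiis(depth=mdiis_depth, damping=damping)
    residuals: list[float] = []
    g_flat: dict = {}
    h_flat: dict = {}
    for it in range(1, max_iter + 1):
        c_k = [rfftn(ci) * dV + cl for ci, cl in zip(c_s, c_long_k)]
        t_s = []
        for j in range(n):
            h_kj = sum(c_k[i] * chi_k[..., i, j] for i in range(n))
            t_kj = h_kj - (c_k[j] - c_long_k[j])
            t_s.append(irfftn(t_kj, s=shape) / dV)
        c_new = []
        g_list = []
        for j, nm in enumerate(names):
            d = minus_beta_us[nm].reshape(shape) + t_s[j]
            g = np.where(d <= 0, np.exp(np.minimum(d, 0.0)), 1.0 + d)
            g_list.append(g)
            c_new.append(g - 1.0 - t_s[j])
        x = np.concatenate([ci.ravel() for ci in c_s])
        r_vec = np.concatenate([(cn - ci).ravel()
                                for cn, ci in zip(c_new, c_s)])
        res = float(np.sqrt(np.mean(r_vec ** 2)))
        residuals.append(res)
        if res < tol:
            for j, nm in enumerate(names):
                g_flat[nm] = g_list[j].ravel()
                h_flat[nm] = (g_list[j] - 1.0).ravel()
            break
        x_new = mdiis.step(x, r_vec)
        c_s = [x_new[k * grid.n_points:(k + 1) * grid.n_points].reshape(shape)
               for k in range(n)]
    else:
        raise RismConvergenceError(
            f"3D-RISM did not converge in {max_iter} iterations at "
            f"lambda={lam_point} (residual {residuals[-1]:.2e})", residuals)

    sol = RismSolution(
        grid=grid, sites=sites, g=g_flat, h=h_flat,
        c_s={nm: ci.ravel() for nm, ci in zip(names, c_s)},
        u_s=u_s, lam_point=lam_point, residual=res, n_iter=it,
        converged=True, solute=list(solute), eta=eta,
        metadata={
            "closure": closure,
            "long_range": "gaussian-split background subtraction",
            "grid_shape": list(shape), "spacing": grid.spacing,
            "mdiis_depth": mdiis_depth, "damping": damping,
        },
    )
    if boundary_tol is not None:
        bmask = grid.boundary_mask().ravel()
        worst = max(float(np.abs(h_flat[nm][bmask]).max()) for nm in names)
        if worst > boundary_tol:
            raise BoxTooSmallError(
                f"boundary |h| = {worst:.3f} exceeds {boundary_tol}; "
                "enlarge the box")
    return sol


def kh_free_energy(
    solution: RismSolution,
    state: ThermodynamicState | None = None,
) -> float:
    """Closed-form KH excess chemical potential of a converged solution:

        mu = kT sum_g rho_g int [ h^2/2 (h<0) - c - h c / 2 ] dV.

    For the KH closure this equals the Kirkwood charging integral (up to
    grid and quadrature error), which is the cross-check used in testing.
    """
    state = state or ThermodynamicState()
    if not solution.converged:
        raise ValueError("KH functional requires a converged solution")
    if solution.lam_point != (1.0, 1.0):
        raise ValueError("KH functional is defined at full coupling")
    dV = solution.grid.cell_volume
    c = solution.c_full(state)
    total = 0.0
    for sv in solution.sites:
        h = solution.h[sv.name]
        integrand = (0.5 * h ** 2 * (h < 0) - c[sv.name]
                     - 0.5 * h * c[sv.name])
        total += sv.density * integrand.sum() * dV
    return state.kt * total


# ---------------------------------------------------------------------------
# Distribution provider for the charging decomposition
# ---------------------------------------------------------------------------

class RismProvider:
    """Wraps the 3-D solver as a distribution provider for the charging
    decomposition, warm-starting each lambda node from the previous one."""

    def __init__(self, solute, susceptibility: SolventSusceptibility,
                 grid: Grid3D, state: ThermodynamicState | None = None,
                 tol: float = 1e-5, max_iter: int = 10000,
                 mdiis_depth: int = 10, damping: float = 0.3,
                 eta: float = DEFAULT_ETA, warm_start: bool = True):
        self.solute = list(solute)
        self.susceptibility = susceptibility
        self.grid = grid
        self.state = state or ThermodynamicState()
        self.tol = tol
        self.max_iter = max_iter
        self.mdiis_depth = mdiis_depth
        self.damping = damping
        self.eta = eta
        self.warm_start = warm_start
        self._prev_c: dict | None = None
        self.last_solution: RismSolution | None = None
        self._volumes = np.full(grid.n_points, grid.cell_volume)

    def solve(self, lam_point) -> RismSolution:
        sol = solve_3d_rism(
            self.solute, self.susceptibility, self.grid, self.state,
            lam_point=lam_point, tol=self.tol, max_iter=self.max_iter,
            mdiis_depth=self.mdiis_depth, damping=self.damping,
            eta=self.eta,
            warm_start=self._prev_c if self.warm_start else None,
        )
        if self.warm_start and lam_point != (0.0, 0.0):
            self._prev_c = sol.c_s
        self.last_solution = sol
        return sol

    def fields(self, lam_point) -> DistributionFields:
        sol = self.solve(lam_point)
        return DistributionFields(points=self.grid.points(),
                                  volumes=self._volumes, g=sol.g)


def rism_provider(solute, susceptibility, grid=None, state=None,
                  **kwargs) -> RismProvider:
    """Convenience factory; builds a default grid around the solute when
    none is given."""
    if grid is None:
        grid = Grid3D.around_solute(solute)
    return RismProvider(solute, susceptibility, grid, state, **kwargs)


# ---------------------------------------------------------------------------
# Text formats
# ---------------------------------------------------------------------------

SUSCEPTIBILITY_FORMAT_VERSION = "1"


def write_susceptibility(sus: SolventSusceptibility, path: str) -> None:
    """Versioned text format: a header naming sites/charges/densities, then
    one row per k with chi for every site pair (column-major pairs)."""
    names = sus.site_names
    with open(path, "w") as fh:
        fh.write(f"# solvmut susceptibility v{SUSCEPTIBILITY_FORMAT_VERSION}"
                 f" provenance={sus.provenance}\n")
        for s in sus.sites:
            fh.write(f"# site {s.name} charge={s.charge} "
                     f"density={s.density} sigma={s.sigma} "
                     f"epsilon={s.epsilon}\n")
        pairs = [(i, j) for i in range(len(names)) for j in range(len(names))]
        fh.write("# k " + " ".join(f"{names[i]}-{names[j]}"
                                   for i, j in pairs) + "\n")
        for m, k in enumerate(sus.k_grid):
            row = [f"{k:.8g}"] + [f"{sus.chi[m, i, j]:.8g}"
                                  for i, j in pairs]
            fh.write(" ".join(row) + "\n")


def read_susceptibility(path: str) -> SolventSusceptibility:
    sites: list[SolventSite] = []
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("# site "):
                parts = line.split()
                name = parts[2]
                kv = dict(p.split("=") for p in parts[3:])
                sites.append(SolventSite(
                    name, float(kv["charge"]), float(kv["density"]),
                    float(kv["sigma"]), float(kv["epsilon"])))
            elif not line.startswith("#") and line.strip():
                rows.append([float(x) for x in line.split()])
    data = np.array(rows)
    n = len(sites)
    chi = data[:, 1:].reshape(len(data), n, n)
    return SolventSusceptibility(sites=sites, k_grid=data[:, 0], chi=chi,
                                 provenance="file")


def write_volumetric(grid: Grid3D, values: np.ndarray, path: str) -> None:
    """Simple volumetric text format: origin, spacing, dims, then values in
    C order, one per line."""
    vals = np.asarray(values).ravel()
    if vals.size != grid.n_points:
        raise ValueError("value count does not match grid")
    with open(path, "w") as fh:
        fh.write("# solvmut volumetric v1\n")
        fh.write(f"origin {grid.origin[0]:.6f} {grid.origin[1]:.6f} "
                 f"{grid.origin[2]:.6f}\n")
        fh.write(f"spacing {grid.spacing:.6f}\n")
        fh.write(f"dims {grid.shape[0]} {grid.shape[1]} {grid.shape[2]}\n")
        for v in vals:
            fh.write(f"{v:.6g}\n")
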