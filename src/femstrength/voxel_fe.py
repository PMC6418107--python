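"""Nonlinear voxel finite-element estimation of hip load capacity.

Each bone voxel of a calibrated QCT volume becomes one 8-node hexahedral
element with isotropic material properties from density power laws.  The
uniaxial constitutive curve has four regions: linear elastic up to the yield
stress, a perfect-plastic plateau, linear strain softening, and a residual
plateau.  Nonlinearity is handled by deformation-theory secant-modulus
iteration on the von Mises effective strain (distortion-energy yield),
appropriate for the monotonic, displacement-controlled loading used here.

Load capacity is obtained by incrementally displacing the femoral-head
surface nodes along the configuration's load direction with the distal face
fully constrained; the capacity (F_NLS for single-limb stance, F_NLF for a
posterolateral fall) is the maximum head reaction force before the force-
displacement curve turns over.

The density power-law constants, load directions, and stance/fall angles are
configuration with documented defaults; capacities are always interpreted
relative to the configured curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.sparse import coo_matrix, csr_matrix
from scipy.sparse.linalg import LinearOperator, cg, splu

from .synth_cohort import QCTVolume

__all__ = [
    "MaterialCurve",
    "HexMesh",
    "SolveConfig",
    "FEResult",
    "MeshConstructionError",
    "SolverError",
    "DEFAULT_LOAD_DIRECTIONS",
    "elastic_modulus",
    "yield_stress",
    "uniaxial_stress",
    "build_mesh",
    "mesh_from_mask",
    "assemble_global_stiffness",
    "element_strains",
    "effective_strain",
    "solve_load_capacity",
    "run_configuration",
]


class MeshConstructionError(RuntimeError):
    pass


class SolverError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# Material law
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MaterialCurve:
    """Density-parameterised uniaxial stress-strain law.

    E(rho) = a * rho**b  [MPa],  sigma_y(rho) = c * rho**d  [MPa], rho in
    g/cm^3 mineral-equivalent density.  Beyond the yield strain the stress
    holds at sigma_y for ``plateau_strain`` of additional strain, then
    softens linearly at ``softening_modulus`` down to
    ``residual_fraction * sigma_y``, where it stays.

    Defaults follow the widely used density power laws for human femoral
    bone (E = 14900 rho^1.86, sigma_y = 102 rho^1.8); they are package
    configuration, not measured constants.
    """

    a: float = 14900.0
    b: float = 1.86
    c: float = 102.0
    d: float = 1.8
    plateau_strain: float = 0.005
    softening_modulus: float = 1000.0
    residual_fraction: float = 0.3
    poisson: float = 0.3

    def __post_init__(self) -> None:
        if self.a <= 0 or self.c <= 0:
            raise ValueError("power-law coefficients must be > 0")
        if not 0 < self.residual_fraction <= 1:
            raise ValueError("residual_fraction must be in (0, 1]")
        if self.softening_modulus <= 0:
            raise ValueError("softening_modulus must be > 0")
        if not 0 <= self.poisson < 0.5:
            raise ValueError("poisson must be in [0, 0.5)")


def elastic_modulus(curve: MaterialCurve, rho) -> np.ndarray:
    """E(rho) in MPa; rho in g/cm^3."""
    return curve.a * np.asarray(rho, dtype=float) ** curve.b


def yield_stress(curve: MaterialCurve, rho) -> np.ndarray:
    """sigma_y(rho) in MPa; rho in g/cm^3."""
    return curve.c * np.asarray(rho, dtype=float) ** curve.d


def uniaxial_stress(curve: MaterialCurve, strain, rho) -> np.ndarray:
    """Evaluate the four-region uniaxial curve at effective strain magnitude
    ``strain`` for density ``rho``.  Vectorised over both arguments;
    continuous and non-negative."""
    eps = np.asarray(strain, dtype=float)
    rho = np.asarray(rho, dtype=float)
    E = elastic_modulus(curve, rho)
    sy = yield_stress(curve, rho)
    eps_y = sy / E
    eps1 = eps_y + curve.plateau_strain
    drop = (1.0 - curve.residual_fraction) * sy
    eps2 = eps1 + drop / curve.softening_modulus
    elastic = E * eps
    softening = sy - curve.softening_modulus * (eps - eps1)
    residual = curve.residual_fraction * sy
    out = np.where(
        eps <= eps_y, elastic,
        np.where(eps <= eps1, sy,
                 np.where(eps <= eps2, softening, residual)))
    return out


def _secant_modulus(curve: MaterialCurve, eps_eff: np.ndarray,
                    E_elastic: np.ndarray, sy: np.ndarray,
                    floor_frac: float) -> np.ndarray:
    """sigma(eps)/eps with the elastic modulus for vanishing strain and a
    relative floor to keep the stiffness matrix nonsingular."""
    tiny = 1e-12
    eps = np.maximum(eps_eff, tiny)
    eps_y = sy / E_elastic
    eps1 = eps_y + curve.plateau_strain
    drop = (1.0 - curve.residual_fraction) * sy
    eps2 = eps1 + drop / curve.softening_modulus
    sig = np.where(
        eps <= eps_y, E_elastic * eps,
        np.where(eps <= eps1, sy,
                 np.where(eps <= eps2,
                          sy - curve.softening_modulus * (eps - eps1),
                          curve.residual_fraction * sy)))
    Es = np.where(eps_eff <= tiny, E_elastic, sig / eps)
    return np.maximum(Es, floor_frac * E_elastic)


# ---------------------------------------------------------------------------
# Mesh
# ---------------------------------------------------------------------------

@dataclass
class HexMesh:
    """Voxel hexahedral mesh: one trilinear element per retained voxel."""

    nodes: np.ndarray              # (N, 3) coordinates, mm
    elements: np.ndarray           # (E, 8) node indices, standard hex order
    element_density: np.ndarray    # (E,) g/cm^3
    node_sets: dict[str, np.ndarray]
    load_direction: np.ndarray     # unit vector
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float)
        self.elements = np.asarray(self.elements, dtype=np.int64)
        self.element_density = np.asarray(self.element_density, dtype=float)
        self.load_direction = np.asarray(self.load_direction, dtype=float)
        n = np.linalg.norm(self.load_direction)
        if n == 0:
            raise ValueError("load_direction must be nonzero")
        self.load_direction = self.load_direction / n
        if self.elements.max(initial=-1) >= len(self.nodes):
            raise ValueError("element refers to missing node")
        head = self.node_sets.get("head_surface", np.array([], int))
        dist = self.node_sets.get("distal_face", np.array([], int))
        if len(head) == 0 or len(dist) == 0:
            raise MeshConstructionError(
                "head_surface and distal_face node sets must be non-empty")
        if np.intersect1d(head, dist).size:
            raise MeshConstructionError(
                "head_surface and distal_face node sets must be disjoint")

    @property
    def n_elements(self) -> int:
        return len(self.elements)


#: Default load directions per configuration (unit vectors in the volume
#: frame x=right/medial, y=anterior, z=superior).  NLS: joint load onto the
#: femoral head tilted 20 degrees from the shaft axis in the coronal plane.
#: NLF: posterolateral impact onto the head, inferiorly and posteriorly
#: directed.  The source protocols do not publish their angles; these are
#: configurable package defaults recorded in result metadata.
DEFAULT_LOAD_DIRECTIONS = {
    "NLS": np.array([np.sin(np.deg2rad(20.0)), 0.0,
                     -np.cos(np.deg2rad(20.0))]),
    "NLF": np.array([-0.2, -0.9, -0.37]) / np.linalg.norm([-0.2, -0.9, -0.37]),
}


def mesh_from_mask(mask: np.ndarray, spacing, density: np.ndarray,
                   head_nodes: np.ndarray, distal_nodes: np.ndarray,
                   load_direction, origin=(0.0, 0.0, 0.0),
                   meta: dict | None = None) -> HexMesh:
    """Build a hex mesh from a boolean voxel mask.  ``density`` is per-voxel
    (same shape, g/cm^3); ``head_nodes``/``distal_nodes`` are indices into
    the compact node numbering this function creates (see
    :func:`build_mesh` for automatic node-set selection)."""
    idx = np.argwhere(mask)
    if idx.size == 0:
        raise MeshConstructionError("no voxels in mask")
    # corner offsets in standard hex order (zeta along z)
    off = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0],
                    [0, 0, 1], [1, 0, 1], [1, 1, 1], [0, 1, 1]])
    corners = idx[:, None, :] + off[None, :, :]       # (E, 8, 3)
    shp = np.asarray(mask.shape) + 1
    flat = np.ravel_multi_index(corners.reshape(-1, 3).T, shp)
    uniq, inv = np.unique(flat, return_inverse=True)
    elements = inv.reshape(-1, 8)
    grid_idx = np.column_stack(np.unravel_index(uniq, shp))
    nodes = np.asarray(origin)[None, :] + grid_idx * np.asarray(spacing)[None, :]
    return HexMesh(
        nodes=nodes, elements=elements,
        element_density=density[mask],
        node_sets={"head_surface": np.asarray(head_nodes, int),
                   "distal_face": np.asarray(distal_nodes, int)},
        load_direction=load_direction, spacing=tuple(spacing),
        meta={"node_grid_index": grid_idx, **(meta or {})},
    )


def build_mesh(volume: QCTVolume, bone_threshold: float = 100.0,
               configuration: str = "NLS",
               load_direction: np.ndarray | None = None,
               head_window_deg: float = 50.0) -> HexMesh:
    """Threshold the calibrated volume, keep the largest face-connected
    component, and mesh it with one element per voxel.

    Node sets: ``distal_face`` is every node on the inferior cut plane of
    the retained component; ``head_surface`` is the femoral-head cap within
    ``head_window_deg`` of the incoming load direction, using the head
    centre/radius from generator metadata (or an estimate from the superior
    bone voxels for external volumes).
    """
    if not volume.calibrated:
        raise ValueError("build_mesh requires a calibrated volume")
    if bone_threshold < 0:
        raise ValueError("bone_threshold must be >= 0")
    if configuration not in ("NLS", "NLF"):
        raise ValueError("configuration must be 'NLS' or 'NLF'")
    mask = volume.grid > bone_threshold
    # exclude phantom rods from the bone mask
    for roi, _ in volume.phantom_rois:
        mask &= ~roi
    if not mask.any():
        raise MeshConstructionError("no voxels above bone threshold")
    labels, nlab = ndimage.label(
        mask, structure=ndimage.generate_binary_structure(3, 1))
    if nlab > 1:
        counts = np.bincount(labels.ravel())[1:]
        mask = labels == (int(np.argmax(counts)) + 1)

    if load_direction is None:
        load_direction = DEFAULT_LOAD_DIRECTIONS[configuration]
    d = np.asarray(load_direction, float)
    d = d / np.linalg.norm(d)

    spacing = np.asarray(volume.spacing)
    origin = np.asarray(volume.meta.get("origin_mm", (0.0, 0.0, 0.0)))
    density = np.maximum(volume.grid, 1.0) / 1000.0  # mg/cc -> g/cm^3

    idx = np.argwhere(mask)
    kmin = idx[:, 2].min()

    # head centre & radius: generator metadata, else estimate from the
    # superior quarter of the bone voxels
    if "head_center_mm" in volume.meta:
        head_c = np.asarray(volume.meta["head_center_mm"], float)
        head_r = float(volume.meta["head_radius_mm"])
    else:
        zmax = idx[:, 2].max()
        top = idx[idx[:, 2] >= kmin + 0.75 * (zmax - kmin)]
        head_c = origin + (top.mean(axis=0) + 0.5) * spacing
        head_r = float(
            np.linalg.norm((top + 0.5) * spacing + origin - head_c,
                           axis=1).max())

    # build elements/nodes first, then pick node sets on node coordinates
    off = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0],
                    [0, 0, 1], [1, 0, 1], [1, 1, 1], [0, 1, 1]])
    corners = idx[:, None, :] + off[None, :, :]
    shp = np.asarray(mask.shape) + 1
    flat = np.ravel_multi_index(corners.reshape(-1, 3).T, shp)
    uniq, inv = np.unique(flat, return_inverse=True)
    elements = inv.reshape(-1, 8)
    grid_idx = np.column_stack(np.unravel_index(uniq, shp))
    nodes = origin[None, :] + grid_idx * spacing[None, :]

    distal = np.flatnonzero(grid_idx[:, 2] == kmin)
    r = nodes - head_c[None, :]
    rn = np.linalg.norm(r, axis=1)
    outward = -d  # cap faces the incoming load
    shell = rn >= head_r - 1.5 * spacing.max()
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = (r @ outward) / np.where(rn > 0, rn, 1.0)
    cap = shell & (cosang >= np.cos(np.deg2rad(head_window_deg)))
    head = np.flatnonzero(cap & ~np.isin(np.arange(len(nodes)), distal))
    if len(head) == 0 or len(distal) == 0:
        raise MeshConstructionError(
            "empty head_surface or distal_face node set; check geometry "
            "metadata and load direction")
    return HexMesh(
        nodes=nodes, elements=elements, element_density=density[mask],
        node_sets={"head_surface": head, "distal_face": distal},
        load_direction=d, spacing=tuple(spacing),
        meta={"configuration": configuration,
              "head_center_mm": tuple(head_c), "head_radius_mm": head_r,
              "bone_threshold": bone_threshold,
              "node_grid_index": grid_idx},
    )


# ---------------------------------------------------------------------------
# Element matrices (rectangular trilinear hexahedron)
# ---------------------------------------------------------------------------

_XI = np.array([[-1, -1, -1], [1, -1, -1], [1, 1, -1], [-1, 1, -1],
                [-1, -1, 1], [1, -1, 1], [1, 1, 1], [-1, 1, 1]], float)


def _b_matrices(h: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """B at the 8 Gauss points plus the Gauss-average B, for a rectangular
    hex with edge lengths ``h``; returns (B_gp (8,6,24), B_avg (6,24), detJ)."""
    g = 1.0 / np.sqrt(3.0)
    B_gp = np.zeros((8, 6, 24))
    for q, (gx, gy, gz) in enumerate(_XI * g):
        dN = np.zeros((8, 3))
        for i, (xi, eta, zeta) in enumerate(_XI):
            dN[i, 0] = 0.125 * xi * (1 + eta * gy) * (1 + zeta * gz) * 2 / h[0]
            dN[i, 1] = 0.125 * eta * (1 + xi * gx) * (1 + zeta * gz) * 2 / h[1]
            dN[i, 2] = 0.125 * zeta * (1 + xi * gx) * (1 + eta * gy) * 2 / h[2]
        B = np.zeros((6, 24))
        for i in range(8):
            B[0, 3 * i] = dN[i, 0]
            B[1, 3 * i + 1] = dN[i, 1]
            B[2, 3 * i + 2] = dN[i, 2]
            B[3, 3 * i] = dN[i, 1]
            B[3, 3 * i + 1] = dN[i, 0]
            B[4, 3 * i + 1] = dN[i, 2]
            B[4, 3 * i + 2] = dN[i, 1]
            B[5, 3 * i] = dN[i, 2]
            B[5, 3 * i + 2] = dN[i, 0]
        B_gp[q] = B
    detJ = h[0] * h[1] * h[2] / 8.0
    return B_gp, B_gp.mean(axis=0), detJ


def _d_matrix(nu: float) -> np.ndarray:
    """Isotropic elasticity matrix for unit Young's modulus."""
    lam = nu / ((1 + nu) * (1 - 2 * nu))
    mu = 1.0 / (2 * (1 + nu))
    D = np.zeros((6, 6))
    D[:3, :3] = lam
    D[np.diag_indices(3)] = lam + 2 * mu
    D[3:, 3:] = np.eye(3) * mu
    return D


def _unit_stiffness(h: np.ndarray, nu: float) -> np.ndarray:
    """24x24 element stiffness for E = 1 MPa (full 8-point Gauss)."""
    B_gp, _, detJ = _b_matrices(h)
    D = _d_matrix(nu)
    K0 = np.zeros((24, 24))
    for q in range(8):
        K0 += B_gp[q].T @ D @ B_gp[q] * detJ
    return K0


def _element_dofs(elements: np.ndarray) -> np.ndarray:
    """(E, 24) global DOF indices."""
    e3 = elements[:, :, None] * 3 + np.arange(3)[None, None, :]
    return e3.reshape(len(elements), 24)


def assemble_global_stiffness(mesh: HexMesh, moduli: np.ndarray,
                              poisson: float) -> csr_matrix:
    """Assemble K from per-element Young's moduli (MPa); units N/mm with
    node coordinates in mm."""
    h = np.asarray(mesh.spacing)
    K0 = _unit_stiffness(h, poisson)
    dofs = _element_dofs(mesh.elements)
    rows = np.repeat(dofs, 24, axis=1).ravel()
    cols = np.tile(dofs, (1, 24)).ravel()
    data = (np.asarray(moduli)[:, None] * K0.ravel()[None, :]).ravel()
    n = 3 * len(mesh.nodes)
    return coo_matrix((data, (rows, cols)), shape=(n, n)).tocsr()


def element_strains(mesh: HexMesh, u: np.ndarray) -> np.ndarray:
    """Gauss-average strain (Voigt, engineering shear) per element, (E, 6)."""
    _, B_avg, _ = _b_matrices(np.asarray(mesh.spacing))
    ue = u[_element_dofs(mesh.elements)]
    return ue @ B_avg.T


def effective_strain(strain_voigt: np.ndarray, poisson: float) -> np.ndarray:
    """Von Mises effective strain, normalised so that it equals the axial
    strain in a uniaxial stress state of a material with the given Poisson
    ratio (the uniaxial curve is then evaluated directly)."""
    e = np.asarray(strain_voigt, dtype=float)
    exx, eyy, ezz = e[..., 0], e[..., 1], e[..., 2]
    exy, eyz, ezx = e[..., 3] / 2, e[..., 4] / 2, e[..., 5] / 2
    m = (exx + eyy + ezz) / 3.0
    dd = ((exx - m) ** 2 + (eyy - m) ** 2 + (ezz - m) ** 2
          + 2 * (exy ** 2 + eyz ** 2 + ezx ** 2))
    vm = np.sqrt(2.0 / 3.0 * dd)
    return vm * 3.0 / (2.0 * (1.0 + poisson))


# ---------------------------------------------------------------------------
# Nonlinear solve
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SolveConfig:
    """Displacement-controlled secant solver settings.

    ``drop_fraction`` operationalises "force began to decrease": loading
    stops once the current reaction falls below (1 - drop_fraction) times
    the running maximum.  ``modulus_floor_frac`` floors each element's
    secant modulus at that fraction of its elastic modulus so fully
    softened elements cannot make the system singular.
    """

    displacement_increment: float = 0.25   # mm per step
    max_steps: int = 40
    secant_tol: float = 1e-3               # relative reaction-force change
    max_secant_iters: int = 20
    drop_fraction: float = 0.02
    modulus_floor_frac: float = 1e-4

    def __post_init__(self) -> None:
        if min(self.displacement_increment, self.max_steps, self.secant_tol,
               self.max_secant_iters, self.modulus_floor_frac) <= 0:
            raise ValueError("all solver settings must be positive")
        if not 0 < self.drop_fraction < 1:
            raise ValueError("drop_fraction must be in (0, 1)")


@dataclass
class FEResult:
    """Force-displacement history and load capacity for one model run."""

    displacements: np.ndarray    # mm, per recorded step
    reaction_forces: np.ndarray  # N
    load_capacity: float         # N, max reaction
    stopped_reason: str          # "force_drop" | "max_steps"
    configuration: str = ""      # "NLS" | "NLF" | ""
    warnings: list[str] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    @property
    def label(self) -> str:
        return {"NLS": "F_NLS", "NLF": "F_NLF"}.get(
            self.configuration, "F")


def solve_load_capacity(mesh: HexMesh, curve: MaterialCurve,
                        cfg: SolveConfig | None = None) -> FEResult:
    """Run the displacement-controlled secant solve and return the reaction
    history and capacity.  Deterministic: no randomness anywhere."""
    cfg = cfg or SolveConfig()
    nu = curve.poisson
    rho = mesh.element_density
    E_el = elastic_modulus(curve, rho)
    sy = yield_stress(curve, rho)

    n_nodes = len(mesh.nodes)
    ndof = 3 * n_nodes
    head = mesh.node_sets["head_surface"]
    distal = mesh.node_sets["distal_face"]
    d = mesh.load_direction

    head_dofs = (head[:, None] * 3 + np.arange(3)).ravel()
    distal_dofs = (distal[:, None] * 3 + np.arange(3)).ravel()
    presc = np.concatenate([head_dofs, distal_dofs])
    free = np.setdiff1d(np.arange(ndof), presc, assume_unique=False)

    h = np.asarray(mesh.spacing)
    K0 = _unit_stiffness(h, nu)
    _, B_avg, _ = _b_matrices(h)
    dofs = _element_dofs(mesh.elements)
    rows = np.repeat(dofs, 24, axis=1).ravel()
    cols = np.tile(dofs, (1, 24)).ravel()
    K0flat = K0.ravel()
    n_el = len(mesh.elements)

    # Partitioned assembly: precompute the entry subsets for K_ff, K_fp and
    # the head-row block (reactions) so each secant iteration only rebuilds
    # small COO matrices instead of slicing the full stiffness matrix.
    new_idx = np.empty(ndof, dtype=np.int64)
    new_idx[free] = np.arange(free.size)
    new_idx[presc] = np.arange(presc.size)
    is_free = np.zeros(ndof, dtype=bool)
    is_free[free] = True
    rf, cf = is_free[rows], is_free[cols]
    sel_ff = rf & cf
    sel_fp = rf & ~cf
    is_head = np.zeros(ndof, dtype=bool)
    is_head[head_dofs] = True
    sel_h = is_head[rows]
    head_pos = np.empty(ndof, dtype=np.int64)
    head_pos[head_dofs] = np.arange(head_dofs.size)
    ij_ff = (new_idx[rows[sel_ff]], new_idx[cols[sel_ff]])
    ij_fp = (new_idx[rows[sel_fp]], new_idx[cols[sel_fp]])
    ij_h = (head_pos[rows[sel_h]], cols[sel_h])

    def assemble(E_sec: np.ndarray):
        data = (E_sec[:, None] * K0flat[None, :]).ravel()
        Kff = coo_matrix((data[sel_ff], ij_ff),
                         shape=(free.size, free.size)).tocsc()
        Kfp = coo_matrix((data[sel_fp], ij_fp),
                         shape=(free.size, presc.size)).tocsr()
        Kh = coo_matrix((data[sel_h], ij_h),
                        shape=(head_dofs.size, ndof)).tocsr()
        return Kff, Kfp, Kh

    E_sec = E_el.copy()
    u = np.zeros(ndof)
    disp_hist: list[float] = []
    force_hist: list[float] = []
    warns: list[str] = []
    running_max = 0.0
    stopped = "max_steps"
    Kff = Kfp = Kh = None
    lu = None
    E_used = None       # moduli the current matrices were assembled from
    E_fact = None       # moduli the current LU factorisation used
    u_f_prev = None

    def _factorise(Kff):
        try:
            return splu(Kff, permc_spec="MMD_AT_PLUS_A",
                        options={"SymmetricMode": True})
        except RuntimeError as exc:  # singular factorisation
            raise SolverError(
                "singular system; check that head_surface and "
                "distal_face constrain a connected mesh") from exc

    def _solve_free(rhs):
        """Direct solve on a fresh factorisation; when the LU is stale
        (moduli drifted < 25% since factorisation) reuse it as a CG
        preconditioner, refactorising only if CG stalls."""
        nonlocal lu, E_fact
        if E_fact is E_used:
            return lu.solve(rhs)
        x, info = cg(Kff, rhs, x0=u_f_prev, rtol=1e-10, maxiter=100,
                     M=LinearOperator(Kff.shape, matvec=lu.solve))
        if info != 0:
            lu = _factorise(Kff)
            E_fact = E_used
            x = lu.solve(rhs)
        return x

    for step in range(1, cfg.max_steps + 1):
        delta = step * cfg.displacement_increment
        u_head = delta * d  # same prescribed vector at every head node
        R = 0.0
        R_prev = None
        converged = False
        for it in range(cfg.max_secant_iters):
            if E_used is None or not np.array_equal(E_sec, E_used):
                Kff, Kfp, Kh = assemble(E_sec)
                E_used = E_sec.copy()
                if free.size and (
                        E_fact is None
                        or np.max(np.abs(E_used - E_fact) / E_el) > 0.25):
                    lu = _factorise(Kff)
                    E_fact = E_used
            u = np.zeros(ndof)
            u[head_dofs] = np.tile(u_head, len(head))
            if free.size:
                u[free] = _solve_free(-(Kfp @ u[presc]))
                u_f_prev = u[free]
            # reaction on the head along the load direction
            R = float(((Kh @ u).reshape(-1, 3) @ d).sum())
            # secant moduli consistent with the new strain state
            eps = element_strains(mesh, u)
            eff = effective_strain(eps, nu)
            E_cand = _secant_modulus(curve, eff, E_el, sy,
                                     cfg.modulus_floor_frac)
            rel_E = float(np.max(np.abs(E_cand - E_sec) / E_el))
            rel_R = (abs(R - R_prev) / max(abs(R), 1e-12)
                     if R_prev is not None else np.inf)
            if rel_E <= cfg.secant_tol or rel_R <= cfg.secant_tol:
                converged = True
                break
            R_prev = R
            # damped update; full steps first, then relax to quench the
            # ping-pong the softening branch can otherwise sustain
            omega = 1.0 if it < 3 else 0.5
            E_sec = np.maximum(E_sec + omega * (E_cand - E_sec),
                               cfg.modulus_floor_frac * E_el)
        if not converged:
            warns.append(f"step {step}: secant loop did not converge")
        disp_hist.append(delta)
        force_hist.append(R)
        running_max = max(running_max, R)
        if R < (1.0 - cfg.drop_fraction) * running_max:
            stopped = "force_drop"
            break

    return FEResult(
        displacements=np.asarray(disp_hist),
        reaction_forces=np.asarray(force_hist),
        load_capacity=float(running_max),
        stopped_reason=stopped,
        warnings=warns,
        meta={"n_elements": mesh.n_elements,
              "n_nodes": n_nodes,
              "load_direction": tuple(float(v) for v in d),
              "solver": "deformation-theory secant, von Mises effective strain",
              "config": {"displacement_increment": cfg.displacement_increment,
                         "max_steps": cfg.max_steps,
                         "drop_fraction": cfg.drop_fraction}},
    )


def run_configuration(volume: QCTVolume, configuration: str,
                      curve: MaterialCurve | None = None,
                      cfg: SolveConfig | None = None,
                      bone_threshold: float = 100.0,
                      load_direction: np.ndarray | None = None) -> FEResult:
    """Convenience composition: mesh the calibrated volume for the given
    loading configuration (NLS stance / NLF posterolateral fall) and solve
    for its load capacity."""
    curve = curve or MaterialCurve()
    mesh = build_mesh(volume, bone_threshold=bone_threshold,
                      configuration=configuration,
                      load_direction=load_direction)
    res = solve_load_capacity(mesh, curve, cfg)
    res.configuration = configuration
    res.meta["subject_id"] = volume.meta.get("subject_id")
    return res
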