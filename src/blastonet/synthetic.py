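"""Synthetic embryo fixtures with known ground-truth contact structure,
plus simulated clinical outcomes.

Cells are icospheres.  Named 4-cell layouts realize each canonical contact
structure with margin from the tangency band at the default 1.05 scale
factor; 8-cell embryos come from a seeded sphere-packing relaxation.
Outcome simulators provide a two-group form (group means/SDs of the
biomarker) and a logistic form (labels drawn from a logistic model of the
biomarker).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import special as sps

from .errors import ConvergenceError, InvalidParameterError
from .meshes import BlastomereMesh, ContactNetwork, Embryo

__all__ = [
    "ArrangementSpec",
    "TwoGroupOutcomeModel",
    "LogisticOutcomeModel",
    "icosphere",
    "generate_arrangement",
    "canonical_centers",
    "analytic_contact_network",
    "pack_spheres",
    "simulate_outcomes",
    "sample_gardner_grades",
    "ARRANGEMENT_LAYOUTS",
]


# ---------------------------------------------------------------------------
# icosphere
# ---------------------------------------------------------------------------


def icosphere(
    radius: float = 1.0,
    center=(0.0, 0.0, 0.0),
    subdivisions: int = 2,
    cell_id: str = "cell",
) -> BlastomereMesh:
    """Unit icosahedron subdivided and projected onto a sphere."""
    if radius <= 0:
        raise InvalidParameterError(f"radius must be positive, got {radius}")
    if subdivisions < 0:
        raise InvalidParameterError("subdivisions must be >= 0")
    phi = (1.0 + math.sqrt(5.0)) / 2.0
    verts = np.array(
        [
            (-1, phi, 0), (1, phi, 0), (-1, -phi, 0), (1, -phi, 0),
            (0, -1, phi), (0, 1, phi), (0, -1, -phi), (0, 1, -phi),
            (phi, 0, -1), (phi, 0, 1), (-phi, 0, -1), (-phi, 0, 1),
        ],
        dtype=np.float64,
    )
    faces = np.array(
        [
            (0, 11, 5), (0, 5, 1), (0, 1, 7), (0, 7, 10), (0, 10, 11),
            (1, 5, 9), (5, 11, 4), (11, 10, 2), (10, 7, 6), (7, 1, 8),
            (3, 9, 4), (3, 4, 2), (3, 2, 6), (3, 6, 8), (3, 8, 9),
            (4, 9, 5), (2, 4, 11), (6, 2, 10), (8, 6, 7), (9, 8, 1),
        ],
        dtype=np.int64,
    )
    verts /= np.linalg.norm(verts, axis=1, keepdims=True)

    for _ in range(subdivisions):
        midpoint: dict[tuple[int, int], int] = {}
        vlist = list(verts)

        def mid(i: int, j: int) -> int:
            key = (min(i, j), max(i, j))
            if key not in midpoint:
                m = vlist[i] + vlist[j]
                m /= np.linalg.norm(m)
                midpoint[key] = len(vlist)
                vlist.append(m)
            return midpoint[key]

        new_faces = []
        for a, b, c in faces:
            ab, bc, ca = mid(a, b), mid(b, c), mid(c, a)
            new_faces += [(a, ab, ca), (b, bc, ab), (c, ca, bc), (ab, bc, ca)]
        verts = np.asarray(vlist)
        faces = np.asarray(new_faces, dtype=np.int64)

    return BlastomereMesh(
        cell_id=cell_id,
        vertices=radius * verts + np.asarray(center, dtype=np.float64),
        faces=faces,
    )


# ---------------------------------------------------------------------------
# canonical layouts (unit-radius cells; scale by radius_mean)
# ---------------------------------------------------------------------------


def _tetrahedral() -> np.ndarray:
    # regular tetrahedron, edge 2
    a = 2.0 / math.sqrt(2.0)
    pts = np.array(
        [(a, 0, -a / math.sqrt(2)), (-a, 0, -a / math.sqrt(2)),
         (0, a, a / math.sqrt(2)), (0, -a, a / math.sqrt(2))]
    )
    # normalize edge length to exactly 2
    d = np.linalg.norm(pts[0] - pts[1])
    return pts * (2.0 / d)


def _planar() -> np.ndarray:
    return np.array([(-1, -1, 0), (1, -1, 0), (1, 1, 0), (-1, 1, 0)], dtype=float)


def _linear() -> np.ndarray:
    return np.array([(-3, 0, 0), (-1, 0, 0), (1, 0, 0), (3, 0, 0)], dtype=float)


def _closed_y() -> np.ndarray:
    # equilateral triangle edge 2 plus a pendant tangent to one vertex
    tri = np.array(
        [(2 / math.sqrt(3), 0, 0),
         (-1 / math.sqrt(3), 1, 0),
         (-1 / math.sqrt(3), -1, 0)]
    )
    u = tri[0] / np.linalg.norm(tri[0])
    pendant = tri[0] + 2.0 * u
    return np.vstack([tri, pendant])


def _pseudotetrahedral() -> np.ndarray:
    # tetrahedron with one edge stretched to 2.2 so exactly one contact
    # breaks at scale factor 1.05 (scaled reach 2.1 < 2.2)
    s3 = math.sqrt(3.0)
    a = np.array((-1.0, 0.0, 0.0))
    b = np.array((1.0, 0.0, 0.0))
    c = np.array((0.0, s3, 0.0))
    y = (6.0 - 2.2 ** 2) / (2.0 * s3)
    z = math.sqrt(3.0 - y * y)
    d = np.array((0.0, y, z))
    return np.vstack([a, b, c, d])


ARRANGEMENT_LAYOUTS = {
    "tetrahedral": _tetrahedral,
    "pseudotetrahedral": _pseudotetrahedral,
    "planar": _planar,
    "closed_y": _closed_y,
    "linear": _linear,
}


def canonical_centers(name: str, radius: float = 1.0) -> np.ndarray:
    """Sphere centers (n, 3) of a named 4-cell layout, scaled to cells of the
    given radius."""
    try:
        layout = ARRANGEMENT_LAYOUTS[name]
    except KeyError:
        raise InvalidParameterError(
            f"unknown arrangement {name!r}; expected one of "
            f"{sorted(ARRANGEMENT_LAYOUTS)} or 'packed_n8'"
        ) from None
    return layout() * radius


def analytic_contact_network(
    centers: np.ndarray, radii: np.ndarray, scale_factor: float = 1.05
) -> ContactNetwork:
    """Ground-truth sphere contact graph: edge iff d_ij < f * (r_i + r_j)."""
    centers = np.asarray(centers, dtype=float)
    radii = np.asarray(radii, dtype=float)
    n = len(centers)
    edges = set()
    for i in range(n):
        for j in range(i + 1, n):
            d = float(np.linalg.norm(centers[i] - centers[j]))
            if d < scale_factor * (radii[i] + radii[j]):
                edges.add((i, j))
    return ContactNetwork(n_nodes=n, edges=frozenset(edges))


# ---------------------------------------------------------------------------
# sphere packing
# ---------------------------------------------------------------------------


def _contact_connected(centers: np.ndarray, radii: np.ndarray, factor: float) -> bool:
    n = len(centers)
    if n == 1:
        return True
    d = np.linalg.norm(centers[:, None, :] - centers[None, :, :], axis=2)
    adj = d < factor * (radii[:, None] + radii[None, :])
    np.fill_diagonal(adj, False)
    seen = {0}
    stack = [0]
    while stack:
        i = stack.pop()
        for j in np.nonzero(adj[i])[0]:
            if j not in seen:
                seen.add(int(j))
                stack.append(int(j))
    return len(seen) == n


def pack_spheres(
    n: int,
    radii,
    seed: int = 0,
    max_iter: int = 5000,
    contact_factor: float = 1.05,
    step: float = 0.05,
) -> np.ndarray:
    """Relax n spheres into a touching, non-overlapping connected cluster.

    Alternates a weak all-pairs attraction with exact pairwise separation
    projections until the pairwise-distance matrix stops changing, no pair
    overlaps (tolerance 1e-6 * mean radius), and the contact graph at
    ``contact_factor`` is connected.  Deterministic given the seed.
    """
    radii = np.asarray(radii, dtype=float)
    if n < 2:
        raise InvalidParameterError("need n >= 2 spheres")
    if len(radii) != n or np.any(radii <= 0):
        raise InvalidParameterError("radii must be n positive values")
    rng = np.random.default_rng(seed)
    rmean = float(radii.mean())
    tol = 1e-6 * rmean

    # seeded start: random directions, loose shell
    centers = rng.normal(size=(n, 3))
    centers /= np.linalg.norm(centers, axis=1, keepdims=True)
    centers *= (2.0 * rmean) * (1.0 + 0.2 * rng.random((n, 1)))

    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    prev_dmat = None
    residual = np.inf
    for _ in range(max_iter):
        # weak mutual attraction: compacts the cluster
        delta = centers[None, :, :] - centers[:, None, :]
        d = np.linalg.norm(delta, axis=2)
        np.fill_diagonal(d, 1.0)
        pull = (delta / d[:, :, None]).sum(axis=1) / max(n - 1, 1)
        centers = centers + step * rmean * pull
        # resolve overlaps by exact pair projection
        for _sweep in range(30):
            moved = False
            for i, j in pairs:
                dl = centers[j] - centers[i]
                dd = float(np.linalg.norm(dl))
                target = radii[i] + radii[j]
                if dd < 1e-9 * rmean:
                    dl = rng.normal(size=3)
                    dl /= np.linalg.norm(dl)
                    dd = 1e-9 * rmean
                if dd < target - tol:
                    u = dl / dd
                    push = 0.5 * (target - dd)
                    centers[i] -= push * u
                    centers[j] += push * u
                    moved = True
            if not moved:
                break
        dmat = np.linalg.norm(centers[:, None, :] - centers[None, :, :], axis=2)
        overlap = (radii[:, None] + radii[None, :]) - dmat
        np.fill_diagonal(overlap, -np.inf)
        residual = float(max(overlap.max(), 0.0))
        if prev_dmat is not None and np.abs(dmat - prev_dmat).max() < 100 * tol:
            if residual <= tol and _contact_connected(centers, radii, contact_factor):
                return centers - centers.mean(axis=0)
        prev_dmat = dmat
    raise ConvergenceError(
        f"sphere packing did not converge in {max_iter} iterations",
        residual=residual,
    )


# ---------------------------------------------------------------------------
# arrangement generation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ArrangementSpec:
    """Recipe for one synthetic embryo."""

    name: str
    n_cells: int = 4
    radius_mean: float = 1.0
    radius_cv: float = 0.0
    jitter_sd: float = 0.0
    mesh_subdivisions: int = 2
    seed: int = 0

    def __post_init__(self):
        if self.radius_mean <= 0:
            raise InvalidParameterError("radius_mean must be positive")
        if self.radius_cv < 0 or self.jitter_sd < 0:
            raise InvalidParameterError("radius_cv and jitter_sd must be >= 0")


def generate_arrangement(spec: ArrangementSpec) -> Embryo:
    """Build an embryo of icosphere cells realizing the named arrangement.

    With ``jitter_sd = 0`` and ``radius_cv = 0`` the mesh-pipeline contact
    network at scale factor 1.05 equals the arrangement's ground-truth
    contact graph exactly.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.name in ARRANGEMENT_LAYOUTS:
        if spec.n_cells != 4:
            raise InvalidParameterError(
                f"arrangement {spec.name!r} requires n_cells = 4"
            )
        centers = canonical_centers(spec.name, spec.radius_mean)
    elif spec.name == "packed_n8" or spec.name == "custom":
        n = spec.n_cells
        radii0 = _draw_radii(rng, n, spec.radius_mean, spec.radius_cv)
        centers = pack_spheres(n, radii0, seed=spec.seed)
    else:
        raise InvalidParameterError(
            f"unknown arrangement {spec.name!r}; expected one of "
            f"{sorted(ARRANGEMENT_LAYOUTS)} or 'packed_n8'"
        )

    n = len(centers)
    if spec.name in ARRANGEMENT_LAYOUTS:
        radii = _draw_radii(rng, n, spec.radius_mean, spec.radius_cv)
    else:
        radii = radii0
    if spec.jitter_sd > 0:
        centers = centers + rng.normal(scale=spec.jitter_sd, size=(n, 3))

    meshes = tuple(
        icosphere(
            radius=float(radii[i]),
            center=centers[i],
            subdivisions=spec.mesh_subdivisions,
            cell_id=f"cell_{i}",
        )
        for i in range(n)
    )
    return Embryo(embryo_id=f"{spec.name}_s{spec.seed}", blastomeres=meshes)


def _draw_radii(rng, n: int, mean: float, cv: float) -> np.ndarray:
    if cv == 0:
        return np.full(n, mean)
    radii = rng.normal(loc=mean, scale=cv * mean, size=n)
    # resample non-physical tails
    floor = 0.2 * mean
    while np.any(radii <= floor):
        bad = radii <= floor
        radii[bad] = rng.normal(loc=mean, scale=cv * mean, size=bad.sum())
    return radii


# ---------------------------------------------------------------------------
# outcome simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TwoGroupOutcomeModel:
    """Gaussian biomarker in positive and negative outcome groups."""

    mean_pos: float
    sd_pos: float
    n_pos: int
    mean_neg: float
    sd_neg: float
    n_neg: int
    truncate: tuple[float, float] | None = None

    def __post_init__(self):
        if self.sd_pos <= 0 or self.sd_neg <= 0:
            raise InvalidParameterError("group SDs must be positive")
        if self.n_pos < 2 or self.n_neg < 2:
            raise InvalidParameterError("group sizes must be >= 2")


@dataclass(frozen=True)
class LogisticOutcomeModel:
    """P(label = 1 | biomarker x) = 1 / (1 + exp(-(intercept + slope * x)))."""

    intercept: float
    slope: float


def _truncated_normal(rng, mean, sd, size, lo, hi):
    out = rng.normal(loc=mean, scale=sd, size=size)
    while np.any((out < lo) | (out > hi)):
        bad = (out < lo) | (out > hi)
        out[bad] = rng.normal(loc=mean, scale=sd, size=bad.sum())
    return out


def simulate_outcomes(model, biomarker=None, seed: int | None = None):
    """Draw (biomarker values, binary labels) from an outcome model.

    Two-group form: ignores ``biomarker`` and generates values and labels
    directly (positives first).  Logistic form: requires ``biomarker`` and
    returns it unchanged alongside Bernoulli labels.
    """
    rng = np.random.default_rng(seed)
    if isinstance(model, TwoGroupOutcomeModel):
        lo, hi = model.truncate if model.truncate is not None else (-np.inf, np.inf)
        pos = _truncated_normal(rng, model.mean_pos, model.sd_pos, model.n_pos, lo, hi)
        neg = _truncated_normal(rng, model.mean_neg, model.sd_neg, model.n_neg, lo, hi)
        values = np.concatenate([pos, neg])
        labels = np.concatenate(
            [np.ones(model.n_pos, dtype=int), np.zeros(model.n_neg, dtype=int)]
        )
        return values, labels
    if isinstance(model, LogisticOutcomeModel):
        if biomarker is None:
            raise InvalidParameterError("logistic form requires biomarker values")
        x = np.asarray(biomarker, dtype=float)
        logit = model.intercept + model.slope * x
        if np.any(~np.isfinite(logit)):
            raise InvalidParameterError("invalid probabilities from logistic model")
        p = sps.expit(logit)
        labels = (rng.random(len(x)) < p).astype(int)
        return x, labels
    raise InvalidParameterError(f"unknown outcome model type: {type(model).__name__}")


_GOOD_GRADES = ("3AA", "4AB", "4BA", "5AB", "3BB")
_POOR_GRADES = ("2AA", "3BC", "3CB", "1CC", "4CC")


def sample_gardner_grades(n: int, p_good: float = 0.55, seed: int | None = None):
    """Categorical sample of Gardner grade strings covering good and poor
    blastocyst quality."""
    if not (0.0 <= p_good <= 1.0):
        raise InvalidParameterError("p_good must be in [0, 1]")
    rng = np.random.default_rng(seed)
    good = rng.random(n) < p_good
    grades = np.where(
        good,
        rng.choice(_GOOD_GRADES, size=n),
        rng.choice(_POOR_GRADES, size=n),
    )
    return list(grades)
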