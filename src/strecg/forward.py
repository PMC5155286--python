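"""Boundary-element forward model: the heart-to-body transfer matrix R.

In a homogeneous, source-free volume conductor bounded outside by the body
surface S_B (insulated: no current leaves the torso) and inside by the
heart surface S_H, Green's second identity applied to Laplace's equation
links the two surface potential distributions.  Collocating at mesh nodes
with linear (vertex-based) shape functions over flat triangles gives

    A_BB y + A_BH x + M_BH g = 0      (observation on S_B)
    A_HB y + A_HH x + M_HH g = 0      (observation on S_H)

where x, y are heart/body node potentials and g is the outward-normal
derivative of the potential on S_H.  The A blocks are double-layer
(solid-angle) integrals, the M blocks single-layer (1/r) integrals.
Eliminating g yields the transfer matrix

    R = -(A_BB - M_BH M_HH^-1 A_HB)^-1 (A_BH - M_BH M_HH^-1 A_HH),

with y = R x, the source-free torso relation.  The same elimination gives
the normal-derivative operator D = -M_HH^-1 (A_HB R + A_HH) mapping x to
g, used as the first-order constraint operator of the baseline methods.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.io as sio
import scipy.linalg as sla

from .mesh import TriangleMesh, read_mesh, solid_angles_batch, write_mesh


class GeometryError(ValueError):
    """Surfaces intersect or are not nested as required."""


class NumericalRankError(np.linalg.LinAlgError):
    """A sub-block of the BEM system is numerically singular."""


# 7-point degree-5 Gauss rule on the unit triangle (barycentric points, weights)
_B7 = np.array([
    [1 / 3, 1 / 3, 1 / 3],
    [0.797426985353087, 0.101286507323456, 0.101286507323456],
    [0.101286507323456, 0.797426985353087, 0.101286507323456],
    [0.101286507323456, 0.101286507323456, 0.797426985353087],
    [0.059715871789770, 0.470142064105115, 0.470142064105115],
    [0.470142064105115, 0.059715871789770, 0.470142064105115],
    [0.470142064105115, 0.470142064105115, 0.059715871789770],
])
_W7 = np.array([0.225,
                0.125939180544827, 0.125939180544827, 0.125939180544827,
                0.132394152788506, 0.132394152788506, 0.132394152788506])

_GL16 = np.polynomial.legendre.leggauss(16)


def _subdivide(tv: np.ndarray) -> np.ndarray:
    """4-way midpoint subdivision of (F, 3, 3) triangles -> (4F, 3, 3)."""
    a, b, c = tv[:, 0], tv[:, 1], tv[:, 2]
    ab, bc, ca = 0.5 * (a + b), 0.5 * (b + c), 0.5 * (c + a)
    return np.concatenate([
        np.stack([a, ab, ca], axis=1),
        np.stack([ab, b, bc], axis=1),
        np.stack([ca, bc, c], axis=1),
        np.stack([ab, bc, ca], axis=1),
    ])


def _quad_layers(p: np.ndarray, tv: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """7-point estimates of single- and double-layer linear-shape integrals.

    Returns (single, double), each (F, 3): per-triangle weights on the three
    corner shape functions for int phi_j / r dS and int phi_j dOmega.
    """
    areas = 0.5 * np.linalg.norm(
        np.cross(tv[:, 1] - tv[:, 0], tv[:, 2] - tv[:, 0]), axis=1)
    nrm = np.cross(tv[:, 1] - tv[:, 0], tv[:, 2] - tv[:, 0])
    nrm = nrm / np.maximum(np.linalg.norm(nrm, axis=1, keepdims=True), 1e-300)
    # quadrature points: (F, Q, 3)
    pts = np.einsum("qk,fkd->fqd", _B7, tv)
    rvec = pts - p
    r = np.linalg.norm(rvec, axis=2)
    inv_r = 1.0 / r
    kappa = np.einsum("fqd,fd->fq", rvec, nrm) * inv_r**3  # solid-angle density
    aw = areas[:, None] * _W7[None, :]
    single = np.einsum("fq,qk,fq->fk", aw, _B7, inv_r)
    double = np.einsum("fq,qk,fq->fk", aw, _B7, kappa)
    return single, double


def _duffy_single(p: np.ndarray, tv_inc: np.ndarray, local: np.ndarray) -> np.ndarray:
    """Single-layer weights for triangles with ``p`` at corner ``local``.

    The radial (Duffy) substitution cancels the 1/r singularity exactly;
    the u-integral is analytic and the v-integral uses 16-point
    Gauss-Legendre.  Returns (F, 3) weights in the triangle's own corner
    order.
    """
    out = np.zeros((len(tv_inc), 3))
    x, w = _GL16
    v = 0.5 * (x + 1.0)
    wv = 0.5 * w
    for f, (tri, loc) in enumerate(zip(tv_inc, local)):
        b, c = tri[(loc + 1) % 3], tri[(loc + 2) % 3]
        area = 0.5 * np.linalg.norm(np.cross(b - tri[loc], c - tri[loc]))
        g = np.linalg.norm((1 - v)[:, None] * (b - p) + v[:, None] * (c - p), axis=1)
        out[f, loc] = area * np.sum(wv / g)
        out[f, (loc + 1) % 3] = area * np.sum(wv * (1 - v) / g)
        out[f, (loc + 2) % 3] = area * np.sum(wv * v / g)
    return out


def _assemble_pair(points: np.ndarray, src: TriangleMesh,
                   incident_node: np.ndarray | None = None
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Double-layer P and single-layer G node matrices for one obs/src pair.

    P[i, j] ~ int_{S} phi_j dOmega(p_i), G[i, j] ~ int_{S} phi_j / r dS.
    Per-triangle double-layer weights are corrected additively so they sum
    to the analytic signed solid angle, keeping the closed-surface
    identities exact.  ``incident_node`` gives, per observation point, its
    node index in ``src`` (same-surface assembly) or -1.
    """
    tv = src.triangle_vertices()
    tris = src.triangles
    n_obs, n_src = len(points), src.node_count
    P = np.zeros((n_obs, n_src))
    G = np.zeros((n_obs, n_src))
    omegas = solid_angles_batch(points, src)  # exact signed solid angles
    diam = np.linalg.norm(tv - np.roll(tv, 1, axis=1), axis=2).max(axis=1)
    cent = tv.mean(axis=1)
    for i, p in enumerate(points):
        inc_node = -1 if incident_node is None else int(incident_node[i])
        inc_mask = np.any(tris == inc_node, axis=1) if inc_node >= 0 else \
            np.zeros(len(tris), dtype=bool)
        dist = np.linalg.norm(cent - p, axis=1)
        near = (~inc_mask) & (dist < 2.0 * diam)
        far = ~(inc_mask | near)

        sw = np.zeros((len(tris), 3))
        dw = np.zeros((len(tris), 3))
        if far.any():
            sw[far], dw[far] = _quad_layers(p, tv[far])
        if near.any():
            # one level of 4-way subdivision for nearly-singular triangles
            sub = _subdivide(_subdivide(tv[near]))
            s_sub, d_sub = _quad_layers(p, sub)
            # children corner weights fold back onto parent linear shapes
            sw[near] = _fold_subdivided(s_sub, near.sum())
            dw[near] = _fold_subdivided(d_sub, near.sum())
        if inc_mask.any():
            loc = np.argmax(tris[inc_mask] == inc_node, axis=1)
            sw[inc_mask] = _duffy_single(p, tv[inc_mask], loc)
            # incident flat triangles subtend zero angle: dw stays 0
        # enforce the exact per-triangle solid angle (additive, shape-preserving)
        dw += (omegas[i] - dw.sum(axis=1))[:, None] / 3.0
        np.add.at(P[i], tris.ravel(), dw.ravel())
        np.add.at(G[i], tris.ravel(), sw.ravel())
    return P, G


# barycentric corners of the 4 children within the parent, per child corner:
# child triangles (a,ab,ca), (ab,b,bc), (ca,bc,c), (ab,bc,ca)
_CHILD_BARY = np.array([
    [[1, 0, 0], [.5, .5, 0], [.5, 0, .5]],
    [[.5, .5, 0], [0, 1, 0], [0, .5, .5]],
    [[.5, 0, .5], [0, .5, .5], [0, 0, 1]],
    [[.5, .5, 0], [0, .5, .5], [.5, 0, .5]],
])


def _fold_subdivided(child_w: np.ndarray, n_parent: int, levels: int = 2) -> np.ndarray:
    """Collapse per-child corner weights back to parent corner shapes."""
    for _ in range(levels):
        m = len(child_w) // 4
        child_w = child_w.reshape(4, m, 3)
        folded = np.einsum("cmj,cjk->mk", child_w, _CHILD_BARY)
        child_w = folded
    assert len(child_w) == n_parent
    return child_w


@dataclass
class TransferModel:
    """BEM coefficient matrices and the assembled transfer matrix.

    Rows of the B-blocks index body-surface nodes, rows of the H-blocks
    heart-surface nodes; columns index nodes of the surface of
    integration.  ``sigma`` is the (uniform) conductivity; it cancels in
    the potential-to-potential relation and is kept as metadata.
    """

    heart: TriangleMesh
    body: TriangleMesh
    A_BB: np.ndarray
    A_BH: np.ndarray
    M_BH: np.ndarray
    A_HH: np.ndarray
    A_HB: np.ndarray
    M_HH: np.ndarray
    sigma: float = 1.0
    R: np.ndarray | None = field(default=None, repr=False)
    cond_R: float | None = None


def _check_nested(heart: TriangleMesh, body: TriangleMesh) -> None:
    inside = solid_angles_batch(heart.vertices, body).sum(axis=1)
    if not np.allclose(inside, 4 * np.pi, atol=1e-3):
        raise GeometryError("heart surface is not strictly inside the body surface")
    outside = solid_angles_batch(body.vertices, heart).sum(axis=1)
    if not np.allclose(outside, 0.0, atol=1e-3):
        raise GeometryError("body surface nodes lie inside the heart surface")


def build_coefficient_matrices(heart: TriangleMesh, body: TriangleMesh,
                               sigma: float = 1.0) -> TransferModel:
    """Assemble the six BEM coefficient matrices for a nested surface pair.

    Both meshes must be closed and outward-oriented, with the heart
    strictly inside the body.  Self-surface solid angles are handled
    analytically (auto solid angle), so each double-layer row satisfies
    the closed-surface identity exactly.
    """
    heart.validate()
    body.validate()
    _check_nested(heart, body)
    four_pi = 4.0 * np.pi

    P_BB, G_BB = _assemble_pair(body.vertices, body,
                                incident_node=np.arange(body.node_count))
    P_BH, G_BH = _assemble_pair(body.vertices, heart)
    P_HB, G_HB = _assemble_pair(heart.vertices, body)
    P_HH, G_HH = _assemble_pair(heart.vertices, heart,
                                incident_node=np.arange(heart.node_count))
    del G_BB, G_HB  # insulated outer boundary: no single layer on S_B

    omega_B = P_BB.sum(axis=1)          # interior solid angle of body at its nodes
    omega_H = P_HH.sum(axis=1)          # interior solid angle of heart at its nodes

    A_BB = (np.diag(omega_B) - P_BB) / four_pi
    A_BH = P_BH / four_pi
    M_BH = G_BH / four_pi
    A_HB = -P_HB / four_pi
    A_HH = (np.diag(four_pi - omega_H) + P_HH) / four_pi
    M_HH = G_HH / four_pi
    return TransferModel(heart=heart, body=body, A_BB=A_BB, A_BH=A_BH, M_BH=M_BH,
                         A_HH=A_HH, A_HB=A_HB, M_HH=M_HH, sigma=sigma)


def assemble_transfer_matrix(model: TransferModel) -> np.ndarray:
    """Eliminate the heart-surface normal derivative and form R (body x heart).

    Also records cond(R) (via singular values) on the model.  The
    Dirichlet-on-S_H / Neumann-on-S_B problem is uniquely solvable, so no
    constant-potential deflation is needed; R maps constants to constants
    (row sums ~ 1).
    """
    try:
        W = sla.solve(model.M_HH, np.hstack([model.A_HB, model.A_HH]))
    except sla.LinAlgError as exc:  # pragma: no cover - defensive
        raise NumericalRankError(f"single-layer heart block is singular: {exc}")
    n_b = model.body.node_count
    W_HB, W_HH = W[:, :n_b], W[:, n_b:]
    lhs = model.A_BB - model.M_BH @ W_HB
    rhs = model.A_BH - model.M_BH @ W_HH
    cond_lhs = np.linalg.cond(lhs)
    if not np.isfinite(cond_lhs) or cond_lhs > 1e12:
        raise NumericalRankError(
            f"body-side BEM block numerically singular (cond={cond_lhs:.3g})")
    R = -sla.solve(lhs, rhs)
    model.R = R
    model.cond_R = float(np.linalg.cond(R))
    return R


def normal_derivative_operator(model: TransferModel) -> np.ndarray:
    """Operator D mapping heart-node potentials to outward-normal derivatives.

    Recovered from the intermediate BEM relation eliminated when forming
    R: g = -M_HH^-1 (A_HB R + A_HH) x.  D 1 ~ 0 (a constant potential
    drives no normal current).
    """
    if model.R is None:
        assemble_transfer_matrix(model)
    return -sla.solve(model.M_HH, model.A_HB @ model.R + model.A_HH)


# ---------------------------------------------------------------------------
# persistence (MatrixMarket + OFF, all text)
# ---------------------------------------------------------------------------

_BLOCKS = ("A_BB", "A_BH", "M_BH", "A_HH", "A_HB", "M_HH")


def save_transfer_model(model: TransferModel, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_mesh(model.heart, directory / "heart.off")
    write_mesh(model.body, directory / "body.off")
    for name in _BLOCKS:
        sio.mmwrite(directory / f"{name}.mtx", getattr(model, name))
    if model.R is not None:
        sio.mmwrite(directory / "R.mtx", model.R)


def load_transfer_model(directory) -> TransferModel:
    directory = Path(directory)
    kw = {name: np.asarray(sio.mmread(directory / f"{name}.mtx"))
          for name in _BLOCKS}
    model = TransferModel(heart=read_mesh(directory / "heart.off"),
                          body=read_mesh(directory / "body.off"), **kw)
    r_path = directory / "R.mtx"
    if r_path.exists():
        model.R = np.asarray(sio.mmread(r_path))
        model.cond_R = float(np.linalg.cond(model.R))
    return model
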