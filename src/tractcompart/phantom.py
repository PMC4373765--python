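"""Synthetic bundle phantom: a curved fiber tract with focal lesions and
distal Wallerian degeneration.

The phantom emulates the geometry and pathophysiology the pipeline is built
to measure: a coherent curved bundle between two anchor ROIs (seed = LGN
end), smoothly varying baseline axial/radial diffusivity along its length,
focal spherical lesions that intersect part of the bundle cross-section and
elevate RD only inside the lesion (demyelination), AD elevation along
lesional fibers distal to the lesion (Wallerian degeneration of transected
axons), and additive Gaussian measurement noise. All generation is
deterministic under a fixed seed.

Default magnitudes follow the study conditions the pipeline targets:
baseline AD 1.32 and RD 0.57 (1e-3 mm^2/s, healthy optic radiation),
within-lesion RD elevation 30%, distal AD elevation 10%, lesion coverage of
half the bundle cross-section, 5% multiplicative noise scale.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq
from scipy.spatial import cKDTree
from scipy.stats import chi2, ncx2, truncnorm

from .io import ScalarVolume, StreamlineBundle, write_scalar_volume, \
    write_streamlines
from .profile import N_NODES

__all__ = [
    "LesionSpec",
    "PhantomConfig",
    "PhantomGroundTruth",
    "PhantomSubject",
    "generate_bundle",
    "generate_fields",
    "generate_subject",
    "generate_cohort",
    "eigenvalue_volumes",
    "third_quarter_lesion_positions",
    "write_subject",
]


@dataclass(frozen=True)
class LesionSpec:
    """One focal lesion: position along the tract and effect sizes.

    ``center_t`` is the arc-length fraction of the lesion center;
    ``coverage`` the fraction of the fiber cross-section it transects;
    ``delta_rd``/``delta_ad`` the fractional elevation inside the lesion.
    """

    center_t: float
    radius_mm: float = 6.0
    coverage: float = 0.5
    delta_rd: float = 0.30
    delta_ad: float = 0.10

    def __post_init__(self):
        if not 0.0 < self.center_t < 1.0:
            raise ValueError("lesion center_t must be in (0, 1)")
        if not 0.0 < self.coverage <= 1.0:
            raise ValueError("coverage must be in (0, 1]")
        if self.delta_rd <= -1 or self.delta_ad <= -1:
            raise ValueError("effect sizes must exceed -1")


def _default_control_points() -> np.ndarray:
    # gentle arc in the x-z plane, ~70 mm long, well inside a 64 mm grid
    return np.array([[12.0, 32.0, 12.0],
                     [44.0, 32.0, 24.0],
                     [48.0, 32.0, 52.0]])


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry, baseline physiology, pathology and noise of one phantom."""

    seed: int
    grid_shape: tuple = (128, 128, 128)
    voxel_size_mm: float = 0.5
    control_points: np.ndarray = field(default_factory=_default_control_points)
    n_fibers: int = 300
    sigma_spread_mm: float = 3.0
    lesions: tuple = (LesionSpec(center_t=0.62),)
    delta_ad_wd: float = 0.10
    noise_sigma: float = 0.05
    ad_baseline: float = 1.32
    rd_baseline: float = 0.57

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        object.__setattr__(self, "control_points",
                           np.asarray(self.control_points, dtype=float))
        object.__setattr__(self, "lesions", tuple(self.lesions))

    # smooth few-percent along-tract variation around the healthy means
    def ad0(self, t):
        t = np.asarray(t, dtype=float)
        return self.ad_baseline * (1 + 0.04 * (t - 0.5) + 0.06 * (t - 0.5) ** 2)

    def rd0(self, t):
        t = np.asarray(t, dtype=float)
        return self.rd_baseline * (1 - 0.03 * (t - 0.5) + 0.08 * (t - 0.5) ** 2)

    @property
    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[0, 0] = aff[1, 1] = aff[2, 2] = self.voxel_size_mm
        return aff


@dataclass
class PhantomGroundTruth:
    """What was injected, on the 50-node template."""

    lesional: np.ndarray              # bool per fiber
    lesion_extents: list              # (start, end) node pairs, 1-based
    delta_rd_nodes: np.ndarray        # injected per-node fractional RD change
    delta_ad_nodes: np.ndarray        # injected per-node fractional AD change
    ad0_nodes: np.ndarray
    rd0_nodes: np.ndarray
    arc_length_mm: float


@dataclass
class PhantomSubject:
    """One phantom subject: inputs the pipeline consumes plus ground truth."""

    subject_id: str
    config: PhantomConfig
    bundle: StreamlineBundle
    ad: ScalarVolume
    rd: ScalarVolume
    lesion_mask: ScalarVolume
    truth: PhantomGroundTruth


class _Centerline:
    """Arc-length parameterized quadratic Bezier with a transported frame."""

    def __init__(self, control_points: np.ndarray, n_dense: int = 400):
        p0, p1, p2 = control_points
        u = np.linspace(0.0, 1.0, n_dense)[:, None]
        pts = (1 - u) ** 2 * p0 + 2 * u * (1 - u) * p1 + u ** 2 * p2
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        arc = np.concatenate([[0.0], np.cumsum(seg)])
        self.length = float(arc[-1])
        self._t = arc / self.length
        self._pts = pts
        tangents = np.gradient(pts, axis=0)
        tangents /= np.linalg.norm(tangents, axis=1, keepdims=True)
        up = np.array([0.0, 1.0, 0.0])
        n1 = np.cross(up, tangents)
        n1 /= np.linalg.norm(n1, axis=1, keepdims=True)
        n2 = np.cross(tangents, n1)
        self._tan, self._n1, self._n2 = tangents, n1, n2

    def _interp(self, array: np.ndarray, t) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t, dtype=float))
        out = np.empty((len(t), 3))
        for dim in range(3):
            out[:, dim] = np.interp(t, self._t, array[:, dim])
        return out

    def point(self, t):
        return self._interp(self._pts, t)

    def frame(self, t):
        n1 = self._interp(self._n1, t)
        n2 = self._interp(self._n2, t)
        n1 /= np.linalg.norm(n1, axis=1, keepdims=True)
        n2 /= np.linalg.norm(n2, axis=1, keepdims=True)
        return n1, n2


def _lesion_center_offset(spec: LesionSpec, sigma: float) -> float:
    """Transverse distance of the lesion center achieving the coverage.

    Fiber offsets are isotropic 2D Gaussian, so the covered fraction of the
    cross-section at center distance d is the noncentral chi-square CDF
    P(|O - d|^2 < r^2). If the requested coverage exceeds what the radius
    can reach, the lesion is centered on the axis.
    """
    r2 = (spec.radius_mm / sigma) ** 2
    max_cov = chi2.cdf(r2, df=2)
    if spec.coverage >= max_cov:
        return 0.0
    f = lambda d: ncx2.cdf(r2, df=2, nc=(d / sigma) ** 2) - spec.coverage
    return brentq(f, 0.0, spec.radius_mm + 8.0 * sigma)


def generate_bundle(config: PhantomConfig,
                    n_points: int = 120) -> StreamlineBundle:
    """Fibers = centerline plus a constant Gaussian transverse offset.

    The anchor is the seed (LGN) end of the centerline; every fiber starts
    there, so orientation is trivially consistent.
    """
    rng = np.random.default_rng(config.seed)
    cl = _Centerline(config.control_points)
    t = np.linspace(0.0, 1.0, n_points)
    base = cl.point(t)
    n1, n2 = cl.frame(t)
    offsets = rng.normal(0.0, config.sigma_spread_mm, size=(config.n_fibers, 2))
    lines = [base + a * n1 + b * n2 for a, b in offsets]
    return StreamlineBundle(lines, anchor=base[0])


def _extent_nodes(t_a: float, t_b: float) -> tuple[int, int]:
    """Map an arc-fraction interval to 1-based nodes under t_k = (k-1)/49."""
    a = int(np.ceil(max(t_a, 0.0) * (N_NODES - 1))) + 1
    b = int(np.floor(min(t_b, 1.0) * (N_NODES - 1))) + 1
    return max(a, 1), min(b, N_NODES)


def generate_fields(config: PhantomConfig, bundle: StreamlineBundle) -> dict:
    """Rasterize baseline + lesion + Wallerian pathology + noise.

    Every voxel gets the arc fraction of its nearest centerline point and
    the baseline AD0(t)/RD0(t). Inside each lesion sphere RD and AD are
    scaled by (1 + delta). The Wallerian territory — the tube swept out by
    the transected fibers distal to the lesion — is evaluated analytically
    as the lesion's transverse disk in the local frame at t beyond the
    lesion's distal border; there AD is scaled by (1 + delta_ad_wd) and RD
    is untouched (demyelination is lesion-confined, degeneration is
    distal). Gaussian noise with sd = noise_sigma * local baseline is
    added last.
    """
    rng = np.random.default_rng(config.seed + 1)
    cl = _Centerline(config.control_points)
    affine = config.affine
    shape = config.grid_shape

    idx = np.indices(shape).reshape(3, -1).T.astype(float)
    world = idx * config.voxel_size_mm  # affine is pure scaling from origin
    dense_t = np.linspace(0.0, 1.0, 600)
    dense_pts = cl.point(dense_t)
    dense_n1, dense_n2 = cl.frame(dense_t)
    _, nearest = cKDTree(dense_pts).query(world, workers=-1)
    t_vox = dense_t[nearest]
    rel = world - dense_pts[nearest]
    off_a = np.einsum("ij,ij->i", rel, dense_n1[nearest])
    off_b = np.einsum("ij,ij->i", rel, dense_n2[nearest])

    ad = config.ad0(t_vox)
    rd = config.rd0(t_vox)
    ad_scale = np.ones_like(ad)
    rd_scale = np.ones_like(rd)
    lesion_mask = np.zeros(len(world), dtype=bool)

    fiber_pts = np.stack(bundle.streamlines)      # (F, P, 3)
    lesional = np.zeros(len(bundle), dtype=bool)
    wd_flat = np.zeros(len(world), dtype=bool)
    extents = []
    delta_rd_nodes = np.zeros(N_NODES)
    delta_ad_nodes = np.zeros(N_NODES)
    node_t = np.arange(N_NODES) / (N_NODES - 1)

    for spec in config.lesions:
        d = _lesion_center_offset(spec, config.sigma_spread_mm)
        n1, _ = cl.frame(spec.center_t)
        center = cl.point(spec.center_t)[0] + d * n1[0]
        grid_mm = np.asarray(shape) * config.voxel_size_mm
        if ((center - spec.radius_mm < 0).any() or
                (center + spec.radius_mm > grid_mm).any()):
            raise ValueError("lesion sphere falls outside the grid")
        in_sphere = np.linalg.norm(world - center, axis=1) < spec.radius_mm
        lesion_mask |= in_sphere
        rd_scale[in_sphere] *= (1 + spec.delta_rd)
        ad_scale[in_sphere] *= (1 + spec.delta_ad)

        # fibers transected by this lesion
        dist = np.linalg.norm(fiber_pts - center, axis=2)     # (F, P)
        hit = (dist < spec.radius_mm).any(axis=1)
        lesional |= hit

        half_t = spec.radius_mm / cl.length
        t_a, t_b = spec.center_t - half_t, spec.center_t + half_t
        extents.append(_extent_nodes(t_a, t_b))
        in_extent = (node_t >= t_a) & (node_t <= t_b)
        delta_rd_nodes[in_extent] = np.maximum(delta_rd_nodes[in_extent],
                                               spec.delta_rd)
        delta_ad_nodes[in_extent] = np.maximum(delta_ad_nodes[in_extent],
                                               spec.delta_ad)
        delta_ad_nodes[node_t > t_b] = np.maximum(
            delta_ad_nodes[node_t > t_b], config.delta_ad_wd)

        # Wallerian territory: the transected fibers' transverse disk,
        # distal to the lesion
        in_disk = (off_a - d) ** 2 + off_b ** 2 < spec.radius_mm ** 2
        wd_flat |= in_disk & (t_vox > t_b)

    wd_flat &= ~lesion_mask
    ad_scale[wd_flat] *= (1 + config.delta_ad_wd)

    ad_field = ad * ad_scale
    rd_field = rd * rd_scale
    if config.noise_sigma > 0:
        ad_field = ad_field + rng.normal(0.0, config.noise_sigma * ad)
        rd_field = rd_field + rng.normal(0.0, config.noise_sigma * rd)

    truth = PhantomGroundTruth(
        lesional=lesional,
        lesion_extents=extents,
        delta_rd_nodes=delta_rd_nodes,
        delta_ad_nodes=delta_ad_nodes,
        ad0_nodes=config.ad0(node_t),
        rd0_nodes=config.rd0(node_t),
        arc_length_mm=cl.length,
    )
    return {
        "AD": ScalarVolume(ad_field.reshape(shape), affine),
        "RD": ScalarVolume(rd_field.reshape(shape), affine),
        "lesion_mask": ScalarVolume(lesion_mask.reshape(shape).astype(float),
                                    affine),
        "truth": truth,
    }


def generate_subject(config: PhantomConfig,
                     subject_id: str = "phantom") -> PhantomSubject:
    """Bundle + fields + ground truth for one phantom subject."""
    bundle = generate_bundle(config)
    fields = generate_fields(config, bundle)
    return PhantomSubject(subject_id, config, bundle, fields["AD"],
                          fields["RD"], fields["lesion_mask"],
                          fields["truth"])


def eigenvalue_volumes(ad: ScalarVolume, rd: ScalarVolume) -> tuple:
    """Emit (l1, l2, l3) eigenvalue volumes with l1 = AD and l2 = l3 = RD.

    Lets the phantom exercise the eigenvalue->metrics path: feeding these
    through the metric computation reproduces AD/RD exactly and defines the
    phantom's MD and FA maps.
    """
    return ad, rd.like(rd.data.copy()), rd.like(rd.data.copy())


def third_quarter_lesion_positions(rng: np.random.Generator,
                                   n: int) -> np.ndarray:
    """Lesion centers concentrated in the third quarter of the tract.

    Truncated normal on (0.1, 0.9), mean 0.62, sd 0.07 — the observed
    preponderance of posterior-mid lesions, none near the seed end.
    """
    lo, hi, mu, sd = 0.1, 0.9, 0.62, 0.07
    a, b = (lo - mu) / sd, (hi - mu) / sd
    return truncnorm.rvs(a, b, loc=mu, scale=sd, size=n, random_state=rng)


def generate_cohort(n_subjects: int, seed: int,
                    config_template: PhantomConfig | None = None,
                    lesion_positions=third_quarter_lesion_positions,
                    p_no_lesion: float = 0.0) -> list[PhantomSubject]:
    """Independent phantom subjects with lesion centers drawn from a
    position distribution; a fraction may carry no lesion at all.

    ``lesion_positions(rng, n)`` must return n arc fractions in (0, 1).
    Deterministic under the top-level seed (child seeds are spawned).
    """
    if config_template is None:
        config_template = PhantomConfig(seed=0)
    master = np.random.default_rng(seed)
    child_seeds = master.integers(0, 2 ** 31 - 1, size=n_subjects)
    subjects = []
    for i, child in enumerate(child_seeds):
        rng = np.random.default_rng(child)
        if p_no_lesion > 0 and rng.random() < p_no_lesion:
            lesions = ()
        else:
            t = float(lesion_positions(rng, 1)[0])
            base = (config_template.lesions[0] if config_template.lesions
                    else LesionSpec(center_t=t))
            lesions = (replace(base, center_t=t),)
        cfg = replace(config_template, seed=int(child), lesions=lesions)
        subjects.append(generate_subject(cfg, subject_id=f"sub-{i + 1:03d}"))
    return subjects


def write_subject(subject: PhantomSubject, out_dir: str | os.PathLike) -> dict:
    """Write one subject's NIfTI/TRK/JSON files; returns the manifest entry."""
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    sid = subject.subject_id
    paths = {
        "bundle": os.path.join(out_dir, f"{sid}_bundle.trk"),
        "ad": os.path.join(out_dir, f"{sid}_ad.nii.gz"),
        "rd": os.path.join(out_dir, f"{sid}_rd.nii.gz"),
        "lesion_mask": os.path.join(out_dir, f"{sid}_lesions.nii.gz"),
        "truth": os.path.join(out_dir, f"{sid}_truth.json"),
    }
    write_streamlines(subject.bundle, paths["bundle"], reference=subject.ad)
    write_scalar_volume(subject.ad, paths["ad"])
    write_scalar_volume(subject.rd, paths["rd"])
    write_scalar_volume(subject.lesion_mask, paths["lesion_mask"])
    truth = subject.truth
    with open(paths["truth"], "w") as fh:
        json.dump({
            "lesional": truth.lesional.astype(int).tolist(),
            "lesion_extents": [list(e) for e in truth.lesion_extents],
            "delta_rd_nodes": truth.delta_rd_nodes.tolist(),
            "delta_ad_nodes": truth.delta_ad_nodes.tolist(),
            "arc_length_mm": truth.arc_length_mm,
            "anchor": subject.bundle.anchor.tolist(),
        }, fh, indent=1)
    return {"subject": sid, **paths}
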