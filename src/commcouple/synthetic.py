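"""Synthetic connectome cohorts with planted, recoverable structure.

Real structural/functional MRI cohorts are access-restricted, so every
analysis in this package is exercised on synthetic data that emulates the
statistical structure the methods assume: spatially embedded sparse SC
with distance-decaying connection probability and weights, FC rows built
as noisy linear mixtures of chosen predictor rows (region- and system-
varying), spherical parcel coordinates for the spin test, and a lifespan
cohort whose planted coupling amplitude declines with age in designated
systems while nuisance covariates drift mildly with age.

FC is generated directly from predictor rows rather than from a
time-series model: the quantities under test are regression recoveries,
not hemodynamics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import minimum_spanning_tree
from sklearn.cluster import KMeans

from .graph_core import ConnectivityMatrix, ParcelGeometry, validate_connectivity
from .predictors import PredictorStack, build_battery, euclidean_matrix

__all__ = [
    "SyntheticConfig",
    "Cohort",
    "generate_geometry",
    "generate_sc",
    "generate_fc",
    "generate_subjects",
    "generate_cohort",
    "fixture_graphs",
    "smooth_maps",
]

#: default system -> planted predictor assignment.  One predictor per class,
#: chosen as the class member most identifiable within the battery (lowest
#: maximum correlation with any other predictor's edge profile), navigation
#: excluded because its non-finite entries make it unusable as a planted
#: signal.  Recovery of a planted label is only well-posed when the label
#: has no near-twin among the 39 competitors.
DEFAULT_PLANTED = ("mfpt-wei", "si-wei-4", "pt-bin", "euc", "pl-wei-4", "fg-wei-10")


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic cohorts.

    ``noise_sd`` is relative to the planted signal SD and applies to
    single-subject fixtures; the lifespan cohort uses ``cohort_noise_sd``
    relative to the *baseline* amplitude, so that the planted age-related
    amplitude decline (losing ``age_decay`` of the coupling across the age
    range in ``decline_systems``) shows up as a decline in variance
    explained.
    """

    n_nodes: int = 100
    n_systems: int = 6
    density: float = 0.15
    distance_decay: float = 0.02  # per mm
    radius: float = 70.0  # mm
    noise_sd: float = 0.1
    amplitude: float = 1.0
    squash_scale: float = 2.5
    planted_map: dict = field(default_factory=dict)
    planted_pairs: dict = field(default_factory=dict)
    # lifespan cohort
    n_subjects: int = 20
    age_range: tuple = (6.0, 85.0)
    age_decay: float = 0.5
    background_decay: float = 0.1
    decline_systems: tuple = ("s1", "s2")
    cohort_noise_sd: float = 0.5
    weight_jitter_sd: float = 0.1

    def system_names(self):
        return [f"s{i + 1}" for i in range(self.n_systems)]

    def planted_label(self, system: str) -> str:
        if self.planted_map:
            return self.planted_map[system]
        i = int(str(system).lstrip("s")) - 1
        return DEFAULT_PLANTED[i % len(DEFAULT_PLANTED)]


@dataclass
class Cohort:
    """A synthetic lifespan cohort: per-subject matrices plus covariates."""

    geometry: ParcelGeometry
    sc: list
    fc: list
    stacks: list
    table: pd.DataFrame
    truth: dict

    @property
    def n_subjects(self) -> int:
        return len(self.sc)

    def node_degrees(self) -> np.ndarray:
        """Per-subject binary and weighted degree, shape (n_sub, N, 2)."""
        out = np.empty((self.n_subjects, self.geometry.n_parcels, 2))
        for s, sc in enumerate(self.sc):
            out[s, :, 0] = (sc.values > 0).sum(axis=1)
            out[s, :, 1] = sc.values.sum(axis=1)
        return out

    def covariate_matrix(self, columns) -> np.ndarray:
        return self.table.loc[:, list(columns)].to_numpy(dtype=float)


def generate_geometry(config: SyntheticConfig, seed: int = 0) -> ParcelGeometry:
    """Jittered parcels on a sphere with spatially contiguous systems.

    Centroids are sampled on a sphere of radius ``config.radius`` with
    radial jitter; systems are angular sectors from k-means on the unit
    vectors, so labels are spatially contiguous; hemispheres follow the
    sign of x.
    """
    rng = np.random.default_rng(seed)
    n = config.n_nodes
    pts = rng.normal(size=(n, 3))
    pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    sphere = pts.copy()
    radii = config.radius * (1.0 + 0.05 * rng.normal(size=n))
    centroids = pts * radii[:, None]
    km = KMeans(n_clusters=config.n_systems, n_init=10,
                random_state=int(rng.integers(2 ** 31 - 1)))
    sectors = _balance_sectors(sphere, km.fit_predict(sphere), config.n_systems)
    names = np.array(config.system_names(), dtype=object)
    return ParcelGeometry(centroids=centroids, sphere_coords=sphere,
                          system_labels=names[sectors])


def _balance_sectors(sphere: np.ndarray, sectors: np.ndarray, k: int) -> np.ndarray:
    """Even out k-means sector sizes to within one parcel of each other by
    moving each oversized sector's most distant parcels to the nearest
    undersized sector, keeping assignments spatially coherent."""
    sectors = sectors.copy()
    n = len(sectors)
    for _ in range(n):
        sizes = np.bincount(sectors, minlength=k)
        if sizes.max() - sizes.min() <= 1:
            break
        big = int(np.argmax(sizes))
        small = int(np.argmin(sizes))
        centers = np.stack([sphere[sectors == c].mean(axis=0) for c in range(k)])
        members = np.where(sectors == big)[0]
        d_small = np.linalg.norm(sphere[members] - centers[small], axis=1)
        sectors[members[np.argmin(d_small)]] = small
    return sectors


def generate_sc(geometry: ParcelGeometry, config: SyntheticConfig,
                seed: int = 0) -> ConnectivityMatrix:
    """Distance-dependent sparse weighted SC, connected by construction.

    Edge presence is Bernoulli with probability proportional to
    ``exp(-decay * distance)``, scaled to hit the target density; weights
    are log-normal attenuated by the same exponential decay.  A minimum
    spanning tree over distances is added so the graph is always a single
    component.
    """
    rng = np.random.default_rng(seed)
    n = geometry.n_parcels
    d = euclidean_matrix(geometry)
    iu = np.triu_indices(n, 1)
    decay = np.exp(-config.distance_decay * d[iu])
    # scale factor hits the target density in expectation
    lo, hi = 0.0, 1e6
    for _ in range(80):
        mid = (lo + hi) / 2
        if np.minimum(1.0, mid * decay).mean() < config.density:
            lo = mid
        else:
            hi = mid
    prob = np.minimum(1.0, lo * decay)
    present = rng.random(len(prob)) < prob
    weights = np.where(present,
                       np.exp(0.5 * rng.normal(size=len(prob))) * decay, 0.0)
    a = np.zeros((n, n))
    a[iu] = weights
    a += a.T
    # guarantee connectivity with an MST over distances
    mst = minimum_spanning_tree(d).toarray()
    mi, mj = np.nonzero(mst)
    for i, j in zip(mi, mj):
        if a[i, j] == 0:
            w = np.exp(0.5 * rng.normal()) * np.exp(-config.distance_decay * d[i, j])
            a[i, j] = a[j, i] = w
    return validate_connectivity(a, kind="structural")


def _planted_signal(stack: PredictorStack, region: int, labels) -> np.ndarray:
    """Z-scored planted predictor row (mean of rows for a planted pair)."""
    parts = []
    for lbl in labels:
        row = stack[lbl][region].astype(float).copy()
        finite = np.isfinite(row)
        finite[region] = False
        if not finite.any():
            raise ValueError(f"planted row of {lbl!r} is non-finite everywhere")
        z = np.zeros_like(row)
        z[finite] = (row[finite] - row[finite].mean()) / row[finite].std()
        parts.append(z)
    return np.mean(parts, axis=0) * np.sqrt(len(parts))


def generate_fc(sc: ConnectivityMatrix, geometry: ParcelGeometry,
                config: SyntheticConfig, seed: int = 0,
                stack: PredictorStack | None = None,
                amplitudes: np.ndarray | None = None,
                noise_abs: np.ndarray | None = None):
    """FC as a noisy linear mixture of planted predictor rows.

    Region i in a system planted with label l gets
    ``FC_i = a_i * z(predictor_l row i) + eps`` with
    ``eps ~ N(0, (noise_sd * a_i)^2)`` unless an absolute noise scale is
    given.  Systems listed in ``config.planted_pairs`` mix two predictor
    rows.  The matrix is symmetrised by averaging and squashed into
    (-1, 1) with a scaled arctangent that preserves rank structure.

    Returns ``(fc, truth)`` where ``truth`` maps region -> planted labels.
    """
    rng = np.random.default_rng(seed)
    if stack is None:
        stack = build_battery(sc, geometry)
    n = sc.n_nodes
    if amplitudes is None:
        amplitudes = np.full(n, config.amplitude)
    if noise_abs is None:
        noise_abs = config.noise_sd * np.asarray(amplitudes, dtype=float)
    noise_abs = np.broadcast_to(np.asarray(noise_abs, dtype=float), (n,))
    raw = np.zeros((n, n))
    truth: dict[int, tuple] = {}
    for i in range(n):
        system = str(geometry.system_labels[i])
        if system in config.planted_pairs:
            labels = tuple(config.planted_pairs[system])
        else:
            labels = (config.planted_label(system),)
        truth[i] = labels
        signal = _planted_signal(stack, i, labels)
        raw[i] = amplitudes[i] * signal + noise_abs[i] * rng.normal(size=n)
        raw[i, i] = 0.0
    sym = (raw + raw.T) / 2.0
    fc = (2.0 / np.pi) * np.arctan((np.pi / 2.0) * sym / config.squash_scale)
    np.fill_diagonal(fc, 0.0)
    return ConnectivityMatrix(values=fc, kind="functional"), truth


def generate_subjects(config: SyntheticConfig, n_subjects: int, seed: int = 0):
    """Independent subjects on a shared parcellation (no age structure).

    Each subject gets a freshly sampled SC, its predictor battery, and FC
    with the configured planted structure.  Returns
    ``(geometry, subjects, truth)`` where ``subjects`` is a list of
    ``(sc, stack, fc)`` triples.
    """
    rng = np.random.default_rng(seed)
    geometry = generate_geometry(config, seed=int(rng.integers(2 ** 31 - 1)))
    subjects = []
    truth = None
    for _ in range(n_subjects):
        sc = generate_sc(geometry, config, seed=int(rng.integers(2 ** 31 - 1)))
        stack = build_battery(sc, geometry)
        fc, truth = generate_fc(sc, geometry, config,
                                seed=int(rng.integers(2 ** 31 - 1)), stack=stack)
        subjects.append((sc, stack, fc))
    return geometry, subjects, truth


def generate_cohort(config: SyntheticConfig, seed: int = 0,
                    keep_stacks: bool = True) -> Cohort:
    """Lifespan cohort with planted age-related coupling decline.

    Ages are uniform over ``config.age_range``.  Each subject's SC jitters
    the weights of a group template (topology fixed); the planted coupling
    amplitude declines linearly with age — by ``config.age_decay`` in
    ``config.decline_systems`` and by the milder ``config.background_decay``
    everywhere else — while the noise stays at ``cohort_noise_sd`` times the
    baseline amplitude, so variance explained falls with age everywhere but
    fastest in the designated systems.  Mean framewise
    displacement drifts upward with age so that nuisance residualisation
    has something to do.
    """
    rng = np.random.default_rng(seed)
    geometry = generate_geometry(config, seed=int(rng.integers(2 ** 31 - 1)))
    template = generate_sc(geometry, config, seed=int(rng.integers(2 ** 31 - 1)))
    n = config.n_nodes
    lo, hi = config.age_range
    ages = np.sort(rng.uniform(lo, hi, config.n_subjects))
    declining = np.isin(geometry.system_labels.astype(str),
                        np.asarray(config.decline_systems, dtype=str))
    sc_list, fc_list, stacks = [], [], []
    rows = []
    truth = None
    for s in range(config.n_subjects):
        jitter = np.exp(config.weight_jitter_sd * rng.normal(size=(n, n)))
        jitter = np.sqrt(jitter * jitter.T)  # keep symmetry
        a = template.values * jitter
        sc = validate_connectivity(a, kind="structural")
        stack = build_battery(sc, geometry)
        frac = (ages[s] - lo) / (hi - lo)
        decay = np.where(declining, config.age_decay, config.background_decay)
        amp = config.amplitude * (1.0 - decay * frac)
        fc, truth = generate_fc(
            sc, geometry, config, seed=int(rng.integers(2 ** 31 - 1)),
            stack=stack, amplitudes=amp,
            noise_abs=np.full(n, config.cohort_noise_sd * config.amplitude))
        sc_list.append(sc)
        fc_list.append(fc)
        stacks.append(stack if keep_stacks else None)
        rows.append({
            "subject_id": f"sub-{s:04d}",
            "age": ages[s],
            "sex": int(rng.integers(2)),
            "visit_time": rng.uniform(8.0, 18.0),
            "n_frames": int(rng.integers(300, 1200)),
            # mild age drift: corr(mean_fd, age) ~ 0.35, as in real cohorts
            "mean_fd": 0.10 + 0.0005 * ages[s] + 0.03 * abs(rng.normal()),
            "total_weight": a.sum() / 2.0,
            "binary_density": (a > 0).sum() / (n * (n - 1)),
        })
    return Cohort(geometry=geometry, sc=sc_list, fc=fc_list, stacks=stacks,
                  table=pd.DataFrame(rows), truth=truth)


# --- tiny fixtures ---------------------------------------------------------

def _ring_geometry(n: int, radius: float = 70.0,
                   arc: float = 2 * np.pi) -> ParcelGeometry:
    ang = np.linspace(0.0, arc, n, endpoint=abs(arc - 2 * np.pi) > 1e-9)
    sphere = np.column_stack([np.cos(ang), np.sin(ang), np.zeros(n)])
    return ParcelGeometry(centroids=radius * sphere, sphere_coords=sphere,
                          system_labels=np.array([f"s{i % 2 + 1}" for i in range(n)]))


def fixture_graphs() -> dict:
    """Named tiny graphs with geometry, used by the oracle tests.

    Includes: a 2-node edge, a 3-node path, the triangle K3, the 4-cycle, a
    5-node star, a weighted triangle with weights {0.1, 1, 1}, and a
    10-node connected geometric graph.
    """
    out: dict[str, tuple] = {}

    def make(name, a, geometry):
        out[name] = (validate_connectivity(np.asarray(a, dtype=float)), geometry)

    make("two_node", [[0, 1], [1, 0]], _ring_geometry(2, arc=np.pi / 3))
    make("path3", [[0, 1, 0], [1, 0, 1], [0, 1, 0]], _ring_geometry(3, arc=np.pi / 2))
    make("k3", [[0, 1, 1], [1, 0, 1], [1, 1, 0]], _ring_geometry(3))
    make("cycle4", [[0, 1, 0, 1], [1, 0, 1, 0], [0, 1, 0, 1], [1, 0, 1, 0]],
         _ring_geometry(4))
    star = np.zeros((5, 5))
    star[0, 1:] = star[1:, 0] = 1.0
    ang = np.linspace(0, 2 * np.pi, 4, endpoint=False)
    sph = np.vstack([[0, 0, 1.0],
                     np.column_stack([np.cos(ang), np.sin(ang), np.zeros(4)])])
    make("star5", star, ParcelGeometry(70 * sph, sph,
                                       np.array(["hub", "s1", "s1", "s2", "s2"])))
    make("weighted_triangle", [[0, 1, 0.1], [1, 0, 1], [0.1, 1, 0]], _ring_geometry(3))

    rng = np.random.default_rng(7)
    cfg = SyntheticConfig(n_nodes=10, n_systems=2, density=0.35)
    geo = generate_geometry(cfg, seed=3)
    sc = generate_sc(geo, cfg, seed=int(rng.integers(2 ** 31 - 1)))
    out["geometric10"] = (sc, geo)
    return out


def smooth_maps(geometry: ParcelGeometry, n_maps: int = 1,
                length_scale: float = 1.0, seed: int = 0) -> np.ndarray:
    """Spatially smooth Gaussian parcel maps (rows), with an isotropic
    exponential covariance in chord distance on the unit sphere — the
    smooth null maps used to check spin-test calibration."""
    rng = np.random.default_rng(seed)
    d = np.linalg.norm(geometry.sphere_coords[:, None]
                       - geometry.sphere_coords[None, :], axis=-1)
    cov = np.exp(-d / length_scale) + 1e-8 * np.eye(geometry.n_parcels)
    chol = np.linalg.cholesky(cov)
    return rng.normal(size=(n_maps, geometry.n_parcels)) @ chol.T
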