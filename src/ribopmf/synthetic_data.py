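"""Synthetic inputs with known ground truth.

Two families of generators live here:

* biased collective-variable samples drawn from p(L) ~ exp(-beta (G(L) + U(L)))
  for analytic free-energy functions G, by grid inverse-CDF, with optional
  AR(1) autocorrelation through a Gaussian copula (the stationary marginal
  is preserved exactly) and an optional planted forward/backward asymmetry
  for hysteresis studies;

* idealized RNA-like base geometries -- regular hexagonal six-membered
  rings plus minimal backbone atoms -- arranged as labelled pairs, stacked
  strands, kissing two-loop complexes and undocking series, for exercising
  the annotation criteria against planted ground truth.

Everything is bit-reproducible given (settings/recipe, seed).
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.stats import norm

from .base_annotation import PairCategory, WcModel, calibrate_wc_model
from .pmf_wham import KB_KCAL_MOL_K
from .structure_io import Atom, Residue, StructureModel
from .umbrella import CvSeries, UmbrellaWindow, WindowSet, bias_energy

__all__ = [
    "AnalyticPmf",
    "SamplerSettings",
    "GeometryRecipe",
    "eval_pmf",
    "sample_window",
    "sample_campaign",
    "raise_docked_well",
    "build_geometry",
    "build_undocking_series",
    "geometry_suite",
    "default_wc_model",
]

RING_RADIUS = 1.39  # Å, regular-hexagon ring
RISE = 3.4  # Å, stacking rise
WC_SEPARATION = 5.7  # Å, canonical ring-centre separation used by the recipes

# ring atoms at 60-degree steps with C2 on the +x axis; the order gives a
# counter-clockwise winding, so the frame normal is +z by construction
_RING_ANGLES = {"N1": -60.0, "C2": 0.0, "N3": 60.0, "C4": 120.0,
                "C5": 180.0, "C6": 240.0}
# minimal backbone stub (local frame) so loop CoM selections are non-empty
_BACKBONE_LOCAL = {"C4'": (-4.2, 0.8, 0.0), "P": (-5.8, 1.6, 0.3),
                   "O3'": (-4.6, -0.6, -0.8)}
_MASSES = {"N": 14.007, "C": 12.011, "P": 30.974, "O": 15.999}

MAX_JITTER = 0.25  # Å; larger jitter can push planted labels across a gate


# ---------------------------------------------------------------------------
# analytic PMFs and biased sampling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnalyticPmf:
    """Ground-truth 1-D free-energy function G(L) on a finite domain."""

    form: str
    domain: tuple[float, float]
    _func: Callable[[np.ndarray], np.ndarray]

    def __call__(self, l_value):
        return eval_pmf(self, l_value)

    @classmethod
    def harmonic(cls, center: float = 12.5, curvature: float = 1.0,
                 domain: tuple[float, float] = (12.0, 34.5)) -> "AnalyticPmf":
        """Single harmonic well G = 1/2 curvature (L - center)^2."""
        return cls("harmonic", domain,
                   lambda l: 0.5 * curvature * (np.asarray(l) - center) ** 2)

    @classmethod
    def double_well(
        cls,
        centers: tuple[float, float] = (15.0, 30.0),
        depths: tuple[float, float] = (9.0, 1.0),
        widths: tuple[float, float] = (1.5, 1.5),
        domain: tuple[float, float] = (12.0, 34.5),
    ) -> "AnalyticPmf":
        """Two Gaussian wells with exact depths at their centers.

        Amplitudes solve a 2x2 linear system so that G(centers[i]) equals
        -depths[i] exactly even when the wells overlap.
        """
        m = np.asarray(centers, float)
        s = np.asarray(widths, float)
        basis = lambda l: -np.exp(  # noqa: E731
            -((np.asarray(l)[..., None] - m) ** 2) / (2 * s**2)
        )
        amplitudes = np.linalg.solve(basis(m), -np.asarray(depths, float))
        return cls("double_well", domain, lambda l: basis(l) @ amplitudes)

    @classmethod
    def well_barrier(
        cls,
        well: tuple[float, float] = (15.0, 8.0),
        barrier: tuple[float, float] = (22.0, 3.0),
        widths: tuple[float, float] = (1.5, 1.5),
        domain: tuple[float, float] = (12.0, 34.5),
    ) -> "AnalyticPmf":
        """One Gaussian well of given depth plus one Gaussian barrier."""
        (mw, dw), (mb, hb) = well, barrier
        sw, sb = widths

        def f(l):
            l = np.asarray(l)
            return -dw * np.exp(-((l - mw) ** 2) / (2 * sw**2)) + hb * np.exp(
                -((l - mb) ** 2) / (2 * sb**2)
            )

        return cls("well_barrier", domain, f)

    @classmethod
    def tabulated(cls, l_nodes: Sequence[float], g_nodes: Sequence[float]) -> "AnalyticPmf":
        """Piecewise-linear interpolation; exact at the table nodes."""
        l_nodes = np.asarray(l_nodes, float)
        g_nodes = np.asarray(g_nodes, float)
        if not np.all(np.diff(l_nodes) > 0):
            raise ValueError("tabulated nodes must have strictly increasing L")
        return cls(
            "tabulated",
            (float(l_nodes[0]), float(l_nodes[-1])),
            lambda l: np.interp(np.asarray(l), l_nodes, g_nodes),
        )


def eval_pmf(pmf: AnalyticPmf, l_value) -> np.ndarray | float:
    """Evaluate G(L) (kcal/mol); raises outside the domain."""
    arr = np.asarray(l_value, dtype=float)
    lo, hi = pmf.domain
    if np.any(arr < lo) or np.any(arr > hi):
        raise ValueError(f"L outside PMF domain [{lo}, {hi}]")
    out = pmf._func(arr)
    return float(out) if np.isscalar(l_value) else np.asarray(out)


def raise_docked_well(
    pmf: AnalyticPmf, shift: float, l_switch: float = 22.0, width: float = 0.5
) -> AnalyticPmf:
    """Raise the PMF below ``l_switch`` by ``shift`` (smooth logistic switch).

    Emulates a pulling protocol that fails to re-form the docked state: the
    docked basin is destabilized by ``shift`` kcal/mol while the undocked
    plateau is untouched.
    """
    base = pmf._func

    def f(l):
        l = np.asarray(l)
        return base(l) + shift / (1.0 + np.exp((l - l_switch) / width))

    return AnalyticPmf(f"{pmf.form}+raised", pmf.domain, f)


@dataclass(frozen=True)
class SamplerSettings:
    seed: int = 0
    n_per_window: int = 5000
    temperature: float = 298.0
    ar1_phi: float = 0.0
    grid_resolution: float = 0.01
    dt_ps: float = 1.0
    t_start_ps: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.ar1_phi < 1.0):
            raise ValueError("ar1_phi must be in [0, 1)")
        if self.n_per_window < 1:
            raise ValueError("n_per_window must be at least 1")
        if self.grid_resolution <= 0 or self.dt_ps <= 0:
            raise ValueError("grid_resolution and dt_ps must be positive")


def _biased_inverse_cdf(
    pmf: AnalyticPmf, window: UmbrellaWindow, settings: SamplerSettings,
    full_k: bool,
) -> tuple[np.ndarray, np.ndarray]:
    """(cdf knots, L knots) of the biased distribution on a fine grid."""
    lo, hi = pmf.domain
    n_cells = max(8, int(np.ceil((hi - lo) / settings.grid_resolution)))
    edges = np.linspace(lo, hi, n_cells + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    beta = 1.0 / (KB_KCAL_MOL_K * settings.temperature)
    log_w = -beta * (
        eval_pmf(pmf, centers) + np.asarray(bias_energy(centers, window, full_k))
    )
    log_w -= log_w.max()
    w = np.exp(log_w)
    total = w.sum()
    if not np.isfinite(total) or total <= 0:
        raise ValueError(
            f"window {window.index}: biased density underflows on the grid"
        )
    cdf = np.concatenate([[0.0], np.cumsum(w) / total])
    cdf[-1] = 1.0
    return cdf, edges


def sample_window(
    pmf: AnalyticPmf,
    window: UmbrellaWindow,
    settings: SamplerSettings,
    stream: int = 0,
    full_k: bool = False,
) -> CvSeries:
    """Draw one window's biased CV samples by grid inverse-CDF.

    With ``ar1_phi > 0`` the uniforms come from a Gaussian AR(1) chain
    pushed through the normal CDF, which correlates successive samples
    while leaving the stationary marginal exactly equal to the target
    biased density.
    """
    lo, hi = pmf.domain
    if not (lo <= window.center <= hi):
        raise ValueError(f"window center {window.center} outside PMF domain")
    cdf, edges = _biased_inverse_cdf(pmf, window, settings, full_k)
    rng = np.random.default_rng([settings.seed, stream, window.index])
    n = settings.n_per_window
    z = rng.standard_normal(n)
    phi = settings.ar1_phi
    if phi > 0.0:
        # stationary AR(1) chain with unit marginal variance
        chain = np.empty(n)
        chain[0] = z[0]
        scale = np.sqrt(1.0 - phi**2)
        for t in range(1, n):
            chain[t] = phi * chain[t - 1] + scale * z[t]
        z = chain
    u = norm.cdf(z)
    values = np.interp(u, cdf, edges)
    times = settings.t_start_ps + settings.dt_ps * np.arange(n)
    return CvSeries(window=window, times=times, values=values)


def sample_campaign(
    pmf: AnalyticPmf,
    windows: WindowSet,
    settings: SamplerSettings,
    hysteresis_shift: float = 0.0,
    l_switch: float = 22.0,
    full_k: bool = False,
) -> list[CvSeries]:
    """One CvSeries per window (in ascending-center order).

    Forward campaigns sample the PMF as given.  Backward campaigns sample a
    PMF whose docked basin (below ``l_switch``) is raised by
    ``hysteresis_shift`` kcal/mol, planting a known asymmetry; with zero
    shift the two directions are statistically identical.
    """
    effective = pmf
    if windows.direction == "backward" and hysteresis_shift != 0.0:
        effective = raise_docked_well(pmf, hysteresis_shift, l_switch)
    stream = 0 if windows.direction == "forward" else 1
    return [
        sample_window(effective, w, settings, stream=stream, full_k=full_k)
        for w in windows.windows
    ]


# ---------------------------------------------------------------------------
# idealized base geometries
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeometryRecipe:
    """A labelled geometry request; recipes carry their ground truth."""

    kind: str
    sequence: str = "GC"
    params: dict = field(default_factory=dict)
    jitter: float = 0.0

    def __post_init__(self) -> None:
        if self.jitter < 0:
            raise ValueError("jitter must be non-negative")
        if self.jitter > MAX_JITTER:
            raise ValueError(
                f"jitter {self.jitter} Å exceeds {MAX_JITTER} Å; planted labels "
                "are no longer guaranteed -- use a smaller jitter"
            )


def _rz(deg: float) -> np.ndarray:
    t = np.deg2rad(deg)
    c, s = np.cos(t), np.sin(t)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _rx(deg: float) -> np.ndarray:
    t = np.deg2rad(deg)
    c, s = np.cos(t), np.sin(t)
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


_FLIP = _rz(180.0)


def _make_residue(
    index: int,
    base: str,
    origin: np.ndarray,
    axes: np.ndarray,
    with_backbone: bool = True,
) -> Residue:
    """One idealized residue: hexagonal ring (+ backbone stub) in a frame.

    ``axes`` rows are the world directions of the residue's local x, y, z.
    """
    res = Residue(index=index, name=base, atoms=[])
    for name, angle in _RING_ANGLES.items():
        local = RING_RADIUS * np.array(
            [np.cos(np.deg2rad(angle)), np.sin(np.deg2rad(angle)), 0.0]
        )
        pos = origin + axes.T @ local
        res.atoms.append(Atom(name, index, base, pos, _MASSES[name[0]]))
    if with_backbone:
        for name, local in _BACKBONE_LOCAL.items():
            pos = origin + axes.T @ np.asarray(local)
            res.atoms.append(Atom(name, index, base, pos, _MASSES[name[0]]))
    return res


def _apply_jitter(model: StructureModel, jitter: float, rng: np.random.Generator) -> None:
    if jitter <= 0:
        return
    for res in model.residues:
        for atom in res.atoms:
            atom.position = atom.position + rng.normal(0.0, jitter, size=3)


def _pair_model(
    sequence: str,
    displacement: Sequence[float],
    flip: bool,
    extra_rotation: np.ndarray | None = None,
    indices: tuple[int, int] = (1, 3),
) -> StructureModel:
    """Two rings: base j at the identity frame, base k displaced by
    ``displacement`` (expressed in frame j) and optionally flipped 180
    degrees about z (pairing) or kept parallel (stacking)."""
    d = np.asarray(displacement, dtype=float)
    axes_j = np.eye(3)
    axes_k = _FLIP.copy() if flip else np.eye(3)
    if extra_rotation is not None:
        axes_k = extra_rotation @ axes_k
    res_j = _make_residue(indices[0], sequence[0], np.zeros(3), axes_j)
    res_k = _make_residue(indices[1], sequence[1], d, axes_k)
    return StructureModel(model_id=1, residues=[res_j, res_k])


def _strand(
    sequence: str,
    start_index: int,
    origin: np.ndarray,
    flip: bool = False,
    twist_deg: float = 0.0,
    rise: float = RISE,
    descending: bool = False,
) -> list[Residue]:
    """A stacked column of rings: rise along +z (or -z), optional twist."""
    residues = []
    for i, base in enumerate(sequence):
        z = -rise * i if descending else rise * i
        axes = _rz(twist_deg * i) @ (_FLIP if flip else np.eye(3))
        residues.append(
            _make_residue(start_index + i, base, origin + np.array([0, 0, z]), axes)
        )
    return residues


def _kissing_model() -> StructureModel:
    """Two 7-residue loops with exactly two planted inter-loop WC pairs.

    Loop A (residues 20-26) is a stacked column at x = 0; loop B (48-54) is
    a flipped stacked column at x = WC_SEPARATION, phased so that 25-49 and
    26-48 sit coplanar at canonical WC separation (G-C both).  All other
    level-matched sequences are non-WC-pairable, so exactly two WC pairs
    exist by construction; each loop contributes six sequential stacks.
    """
    seq_a = "AAAAAGG"  # residues 20..26; G at 25, 26
    res_a = _strand(seq_a, 20, np.zeros(3))
    z25 = RISE * 5
    origin_48 = np.array([WC_SEPARATION, 0.0, z25 + RISE])
    res_b = _strand("C" + "CAAAAA", 48, origin_48, flip=True, descending=True)
    return StructureModel(model_id=1, residues=res_a + res_b)


def build_geometry(recipe: GeometryRecipe, seed: int = 0):
    """Construct a labelled idealized geometry.

    Returns a :class:`StructureModel` for single-model kinds and a list of
    models for ``undocking_series``.  Jitter adds seeded Gaussian noise to
    every atom position.
    """
    rng = np.random.default_rng([seed, len(recipe.kind)])
    p = recipe.params
    kind = recipe.kind
    if kind == "wc_pair":
        d = p.get("displacement", (WC_SEPARATION, 0.0, 0.0))
        model = _pair_model(recipe.sequence, d, flip=True)
    elif kind == "noncanonical_pair":
        d = p.get("displacement", (4.0, 0.0, 0.5))
        model = _pair_model(recipe.sequence, d, flip=True)
    elif kind == "stack":
        d = p.get("displacement", (0.5, 0.0, RISE))
        model = _pair_model(recipe.sequence, d, flip=False)
    elif kind == "none":
        d = p.get("displacement", (9.0, 0.0, 0.0))
        model = _pair_model(recipe.sequence, d, flip=p.get("flip", True))
    elif kind == "aform_strand":
        seq = recipe.sequence if len(recipe.sequence) > 2 else "GCAUGCA"
        residues = _strand(seq, p.get("start_index", 1), np.zeros(3),
                           twist_deg=p.get("twist_deg", 32.0))
        model = StructureModel(model_id=1, residues=residues)
    elif kind == "kissing_complex":
        model = _kissing_model()
    elif kind == "undocking_series":
        return build_undocking_series(
            p.get("separations", (12.5, 20.0, 34.0)), recipe.jitter, seed
        )
    else:
        raise ValueError(f"unknown geometry kind {recipe.kind!r}")
    _apply_jitter(model, recipe.jitter, rng)
    return model


def build_undocking_series(
    separations: Sequence[float], jitter: float = 0.0, seed: int = 0
) -> list[StructureModel]:
    """Kissing-complex models rigidly pulled apart to exact CoM separations.

    Loop B (residues 48-54) is translated along the current CoM-difference
    direction so that ``loop_distance`` reproduces each requested
    separation exactly (up to float rounding).
    """
    from .structure_io import LoopDefinition, backbone_com

    loop_a = LoopDefinition("L2", (20, 26))
    loop_b = LoopDefinition("L3", (48, 54))
    rng = np.random.default_rng([seed, 99])
    models = []
    for m, target in enumerate(separations, start=1):
        model = _kissing_model()
        model.model_id = m
        com_a = backbone_com(model, loop_a)
        com_b = backbone_com(model, loop_b)
        delta = com_b - com_a
        d0 = np.linalg.norm(delta)
        shift = (target - d0) * delta / d0
        for res in model.residues:
            if 48 <= res.index <= 54:
                for atom in res.atoms:
                    atom.position = atom.position + shift
        _apply_jitter(model, jitter, rng)
        models.append(model)
    return models


# ---------------------------------------------------------------------------
# labelled classification suite and the shipped WC model
# ---------------------------------------------------------------------------

def geometry_suite() -> list[tuple[StructureModel, PairCategory, tuple[int, int]]]:
    """Deterministic labelled two-base geometries covering all categories.

    Over 100 cases, including near-boundary ones kept at least 0.3 Å away
    from every decision surface, so a correct classifier scores 100%.
    """
    cases: list[tuple[StructureModel, PairCategory, tuple[int, int]]] = []

    def add(kind, seq, d, flip, label):
        model = _pair_model(seq, d, flip=flip)
        cases.append((model, label, (1, 3)))

    # Watson-Crick: canonical sequences near the calibrated geometry
    for seq in ("GC", "CG", "AU", "UA"):
        for dx in (5.5, 5.7, 5.9):
            for dy in (-0.2, 0.0, 0.2):
                add("wc", seq, (dx, dy, 0.0), True, PairCategory.WC)
    # non-canonical: in-plane, inside the ellipsoid, |z| well below 2
    for seq in ("GA", "AA", "GU", "CU"):
        for dx in (3.5, 4.0, 4.5):
            for dz in (-1.2, 0.0, 1.2):
                add("nc", seq, (dx, 0.0, dz), True, PairCategory.NONCANONICAL)
    # non-canonical with WC-able sequence but far from the WC geometry
    for seq in ("GC", "AU"):
        for d in ((0.0, 4.0, 0.5), (2.0, -3.5, 1.0), (-4.0, 0.0, 0.0)):
            add("nc", seq, d, True, PairCategory.NONCANONICAL)
    # stacking: parallel rings, |z| >= 2.3, in-plane offset <= 1.8
    for seq in ("GC", "AG", "UU"):
        for dz in (2.6, 3.0, 3.4, -3.0):
            for dxy in ((0.0, 0.0), (1.0, 0.0), (0.0, 1.4), (1.0, 1.0)):
                add("st", seq, (*dxy, dz), False, PairCategory.STACKING)
    # no contact: outside the ellipsoid or off the stacking column
    for seq in ("GC", "GA"):
        for d, flip in (
            ((9.0, 0.0, 0.0), True),
            ((0.0, 9.0, 0.0), True),
            ((0.0, 0.0, 6.0), False),
            ((3.5, 3.0, 2.8), False),   # z-displaced but rho^2 >> 5
            ((7.5, 4.0, 1.0), True),    # D > 2.5 on both sides
            ((12.0, 0.0, 3.0), False),
        ):
            add("no", seq, d, flip, PairCategory.NONE)
    return cases


@functools.lru_cache(maxsize=1)
def default_wc_model() -> WcModel:
    """WcModel calibrated on idealized jittered WC geometries (fixed seed).

    The canonical relative position is (WC_SEPARATION, 0, 0) in both
    frames; calibration examples vary the separation, in-plane offset,
    rise and propeller/buckle angles and pool both r_jk and r_kj.
    """
    from .base_annotation import build_frame, relative_position

    rng = np.random.default_rng(987654321)
    examples = []
    for _ in range(400):
        d = np.array([WC_SEPARATION, 0.0, 0.0]) + rng.normal(
            0.0, [0.25, 0.25, 0.18]
        )
        extra = _rx(rng.normal(0.0, 8.0)) @ _rz(rng.normal(0.0, 8.0))
        model = _pair_model("GC", d, flip=True, extra_rotation=extra)
        frame_j = build_frame(model.residues[0])
        frame_k = build_frame(model.residues[1])
        examples.append(relative_position(frame_j, frame_k))
        examples.append(relative_position(frame_k, frame_j))
    return calibrate_wc_model(examples)
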