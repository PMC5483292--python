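"""Binocular pre-alignment and two-stage GA affine registration.

Subjects' heads are deliberately not restrained during thermal acquisition,
so consecutive frames drift by small rigid-plus-scale motions.  Each frame
is aligned to a fixed reference built from the first frame:

1. the two eye regions (local cold spots inside the face) are located by
   intensity-weighted center of mass, and the first frame is translated
   (and horizontally flipped, if the acquisition was mirrored) so the
   binocular midpoint sits at a canonical position;
2. a two-stage real-coded genetic algorithm then maximises an overlap
   fitness for every frame: stage 1 searches translation + rotation over
   wide bounds, stage 2 refines all six affine parameters in a narrow
   neighbourhood of the stage-1 optimum.

The fitness is the negative mean absolute temperature difference over the
fixed image's face mask — robust, smooth enough near the optimum, and in
the same °C units as the reported overlap error.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import AffineParams, ThermalSequence, ThermofaceError


class RegistrationError(ThermofaceError):
    pass


# --------------------------------------------------------------------------
# Affine warping


def apply_affine(frame: np.ndarray, params: AffineParams, fill: float = 0.0) -> np.ndarray:
    """Warp a frame by an affine transform about the image center.

    Bilinear interpolation; pixels mapping outside the input domain are set
    to ``fill``.  Identity parameters return the input values bit-exactly.
    """
    frame = np.asarray(frame, dtype=float)
    if params.is_identity:
        return frame.copy()
    rows, cols = frame.shape
    c = np.array([(cols - 1) / 2.0, (rows - 1) / 2.0])
    m = params.linear_matrix()
    m_inv = np.linalg.inv(m)
    t = np.array([params.tx, params.ty])
    # forward: out = M (in - c) + c + t  =>  in = M^-1 (out - c - t) + c
    b_xy = c - m_inv @ (c + t)
    a_rc = np.array([[m_inv[1, 1], m_inv[1, 0]], [m_inv[0, 1], m_inv[0, 0]]])
    b_rc = np.array([b_xy[1], b_xy[0]])
    return ndimage.affine_transform(
        frame, a_rc, offset=b_rc, order=1, mode="constant", cval=fill, prefilter=False
    )


# --------------------------------------------------------------------------
# Binocular localization


def _face_mask(frame: np.ndarray, bg_threshold: float) -> np.ndarray:
    return frame > bg_threshold


def _eye_components(
    frame: np.ndarray,
    bg_threshold: float,
    margin: float,
    min_area: int,
) -> list[tuple[np.ndarray, float, float, float]]:
    """Candidate eye blobs: ``(weights image, mass, cx, cy)`` per component,
    two largest by mass, sorted left to right."""
    mask = _face_mask(frame, bg_threshold)
    if not mask.any():
        raise RegistrationError("binocular localization failed: no face pixels")
    med = float(np.median(frame[mask]))
    cold = mask & (frame < med - margin)
    labels, n = ndimage.label(cold)
    comps = []
    for lab in range(1, n + 1):
        sel = labels == lab
        if sel.sum() < min_area:
            continue
        w = np.where(sel, med - frame, 0.0)
        mass = float(w.sum())
        ys, xs = np.nonzero(sel)
        cx = float((w[ys, xs] * xs).sum() / mass)
        cy = float((w[ys, xs] * ys).sum() / mass)
        comps.append((w, mass, cx, cy))
    if len(comps) < 2:
        raise RegistrationError(
            f"binocular localization failed: {len(comps)} candidate region(s)"
        )
    comps.sort(key=lambda c: c[1], reverse=True)
    comps = comps[:2]
    comps.sort(key=lambda c: c[2])
    return comps


def locate_binocular_centers(
    frame: np.ndarray,
    bg_threshold: float = 28.5,
    margin: float = 2.0,
    min_area: int = 5,
) -> tuple[tuple[float, float], tuple[float, float]]:
    """Sub-pixel intensity-weighted centroids of the two eye regions.

    Eye candidates are pixels colder than the face-mask median by ``margin``
    °C; the two largest connected components are taken as the eyes.  Returns
    ``(left, right)`` as (x, y), left = smaller column.  Raises
    :class:`RegistrationError` when fewer than two candidates survive.
    """
    comps = _eye_components(frame, bg_threshold, margin, min_area)
    return (comps[0][2], comps[0][3]), (comps[1][2], comps[1][3])


def canonical_midpoint(shape: tuple[int, int]) -> tuple[float, float]:
    """Canonical binocular midpoint: horizontal center, 5/12 of the height."""
    rows, cols = shape
    return cols / 2.0, rows * 5.0 / 12.0


def build_fixed_image(
    sequence: ThermalSequence,
    bg_threshold: float = 28.5,
    margin: float = 2.0,
    min_area: int = 5,
) -> np.ndarray:
    """Reference frame for registration, from the sequence's first frame.

    The frame is horizontally flipped if the acquisition appears mirrored
    (heavier eye blob on the right — faces are mildly asymmetric and the
    heavier blob is canonically the left eye), then translated so the
    binocular midpoint sits at the canonical position.  A frame already in
    canonical pose is returned unchanged.
    """
    frame = np.asarray(sequence.frames[0], dtype=float)
    comps = _eye_components(frame, bg_threshold, margin, min_area)
    if comps[0][1] < comps[1][1]:  # left blob lighter than right: mirrored
        frame = frame[:, ::-1].copy()
        comps = _eye_components(frame, bg_threshold, margin, min_area)
    mx = (comps[0][2] + comps[1][2]) / 2.0
    my = (comps[0][3] + comps[1][3]) / 2.0
    cx, cy = canonical_midpoint(frame.shape)
    dx, dy = cx - mx, cy - my
    if abs(dx) < 1e-6 and abs(dy) < 1e-6:
        return frame
    mask = _face_mask(frame, bg_threshold)
    fill = float(np.median(frame[~mask])) if (~mask).any() else float(frame.min())
    return apply_affine(frame, AffineParams(tx=dx, ty=dy), fill=fill)


# --------------------------------------------------------------------------
# Genetic algorithm


@dataclass
class GaConfig:
    """Hyperparameters of the two-stage GA search."""

    population: int = 50
    generations: int = 60
    crossover_rate: float = 0.8
    mutation_rate: float = 0.1
    mutation_sd_frac: float = 0.1  # sd as fraction of each bound's width
    tournament_k: int = 3
    elitism: int = 2
    stage1_translation: float = 15.0  # |tx|, |ty| bound, px
    stage1_rotation: float = 10.0  # |theta| bound, degrees
    stage2_translation: float = 3.0  # half-widths around stage-1 optimum
    stage2_rotation: float = 2.0
    stage2_scale: float = 0.05
    stage2_shear: float = 0.05
    bg_threshold: float = 28.5
    remove_median_offset: bool = False
    fitness: str = "neg_mad"
    seed: int = 0

    def __post_init__(self) -> None:
        for r in (self.crossover_rate, self.mutation_rate):
            if not 0.0 <= r <= 1.0:
                raise RegistrationError("GA rates must lie in [0, 1]")
        if self.elitism >= self.population:
            raise RegistrationError("elitism must be smaller than population")


def _run_ga(
    fitness_fn: Callable[[np.ndarray], float],
    lo: np.ndarray,
    hi: np.ndarray,
    config: GaConfig,
    rng: np.random.Generator,
    seeds: Sequence[np.ndarray] = (),
) -> tuple[np.ndarray, list[float]]:
    """Real-coded GA: tournament selection, uniform crossover, Gaussian
    mutation, elitism.  Returns best genes and per-generation best fitness."""
    n_genes = len(lo)
    width = hi - lo
    pop = rng.uniform(lo, hi, size=(config.population, n_genes))
    for i, s in enumerate(seeds):
        pop[i % config.population] = np.clip(s, lo, hi)
    fit = np.array([fitness_fn(ind) for ind in pop])
    trace: list[float] = []
    for _ in range(config.generations):
        order = np.argsort(fit)[::-1]
        pop, fit = pop[order], fit[order]
        trace.append(float(fit[0]))
        new = [pop[i].copy() for i in range(config.elitism)]
        while len(new) < config.population:
            idx1 = rng.integers(0, config.population, size=config.tournament_k)
            idx2 = rng.integers(0, config.population, size=config.tournament_k)
            p1 = pop[idx1[np.argmax(fit[idx1])]]
            p2 = pop[idx2[np.argmax(fit[idx2])]]
            child = p1.copy()
            if rng.random() < config.crossover_rate:
                take = rng.random(n_genes) < 0.5
                child[take] = p2[take]
            mutate = rng.random(n_genes) < config.mutation_rate
            child[mutate] += rng.normal(0.0, config.mutation_sd_frac * width[mutate])
            new.append(np.clip(child, lo, hi))
        pop = np.array(new)
        fit = np.concatenate(
            [fit[: config.elitism], [fitness_fn(ind) for ind in pop[config.elitism :]]]
        )
    best = int(np.argmax(fit))
    trace.append(float(fit[best]))
    return pop[best], trace


def _make_fitness(
    moving: np.ndarray, fixed: np.ndarray, mask: np.ndarray, fill: float, config: GaConfig
) -> Callable[[AffineParams], float]:
    fixed_vals = fixed[mask]

    def fitness(params: AffineParams) -> float:
        warped = apply_affine(moving, params, fill=fill)
        diff = warped[mask] - fixed_vals
        if config.remove_median_offset:
            diff = diff - np.median(diff)
        return -float(np.mean(np.abs(diff)))

    return fitness


def ga_affine_register(
    moving: np.ndarray,
    fixed: np.ndarray,
    config: GaConfig | None = None,
    init: AffineParams | None = None,
    seed: int | None = None,
) -> tuple[AffineParams, list[float]]:
    """Register one frame to the fixed image with the two-stage GA.

    Stage 1 searches (tx, ty, theta) over wide bounds; stage 2 refines all
    six parameters within narrow bounds centered on the stage-1 optimum.
    With ``init`` given (warm start), stage 1 is skipped and stage 2 is
    centered on ``init``.  Deterministic given the seed; the returned trace
    of per-generation best fitness is non-decreasing.
    """
    config = config or GaConfig()
    moving = np.asarray(moving, dtype=float)
    fixed = np.asarray(fixed, dtype=float)
    if moving.shape != fixed.shape:
        raise RegistrationError("moving and fixed frames must share a shape")
    mask = _face_mask(fixed, config.bg_threshold)
    if not mask.any() or float(fixed[mask].std()) == 0.0:
        raise RegistrationError("degenerate fixed image: no contrast over face mask")
    fill = float(np.median(fixed[~mask])) if (~mask).any() else float(fixed.min())
    fitness = _make_fitness(moving, fixed, mask, fill, config)
    rng = np.random.default_rng(config.seed if seed is None else seed)

    trace: list[float] = []
    if init is None:
        lo1 = np.array([-config.stage1_translation, -config.stage1_translation, -config.stage1_rotation])
        hi1 = -lo1
        f1 = lambda g: fitness(AffineParams(tx=g[0], ty=g[1], theta=g[2]))
        best1, tr1 = _run_ga(f1, lo1, hi1, config, rng, seeds=[np.zeros(3)])
        center = AffineParams(tx=best1[0], ty=best1[1], theta=best1[2])
        trace += tr1
    else:
        center = init

    c = np.array([center.tx, center.ty, center.theta, center.sx, center.sy, center.shear])
    half = np.array(
        [
            config.stage2_translation,
            config.stage2_translation,
            config.stage2_rotation,
            config.stage2_scale,
            config.stage2_scale,
            config.stage2_shear,
        ]
    )
    lo2, hi2 = c - half, c + half
    lo2[3:5] = np.maximum(lo2[3:5], 1e-3)

    def f2(g: np.ndarray) -> float:
        return fitness(AffineParams(tx=g[0], ty=g[1], theta=g[2], sx=g[3], sy=g[4], shear=g[5]))

    best2, tr2 = _run_ga(f2, lo2, hi2, config, rng, seeds=[c])
    trace += tr2
    params = AffineParams(
        tx=float(best2[0]),
        ty=float(best2[1]),
        theta=float(best2[2]),
        sx=float(best2[3]),
        sy=float(best2[4]),
        shear=float(best2[5]),
    )
    return params, trace


# --------------------------------------------------------------------------
# Sequence registration


@dataclass
class RegistrationResult:
    """Per-frame registration outcome for one sequence."""

    params: list[AffineParams]
    fitness: list[float]
    err_before: np.ndarray  # mean |moving - fixed| over face mask, °C
    err_after: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "frame": i,
                "tx": p.tx,
                "ty": p.ty,
                "theta": p.theta,
                "sx": p.sx,
                "sy": p.sy,
                "shear": p.shear,
                "fitness": f,
                "err_before": float(b),
                "err_after": float(a),
            }
            for i, (p, f, b, a) in enumerate(
                zip(self.params, self.fitness, self.err_before, self.err_after)
            )
        ]
        return pd.DataFrame(rows)


def register_sequence(
    sequence: ThermalSequence,
    config: GaConfig | None = None,
    warm_start: bool = True,
) -> tuple[ThermalSequence, RegistrationResult]:
    """Register every frame of a sequence to its fixed image.

    With ``warm_start`` (default) each frame after the first skips stage 1
    and refines around the previous frame's solution — head motion between
    consecutive frames is small.  Reports the overlap error (mean absolute
    temperature difference over the face mask) before and after per frame.
    """
    config = config or GaConfig()
    fixed = build_fixed_image(sequence, bg_threshold=config.bg_threshold)
    mask = _face_mask(fixed, config.bg_threshold)
    fill = float(np.median(fixed[~mask])) if (~mask).any() else float(fixed.min())
    fixed_vals = fixed[mask]

    params_list: list[AffineParams] = []
    fitness_list: list[float] = []
    err_before = np.empty(sequence.n_frames)
    err_after = np.empty(sequence.n_frames)
    registered = np.empty_like(sequence.frames, dtype=float)
    prev: AffineParams | None = None
    for i in range(sequence.n_frames):
        moving = np.asarray(sequence.frames[i], dtype=float)
        try:
            init = prev if (warm_start and prev is not None) else None
            params, trace = ga_affine_register(
                moving, fixed, config, init=init, seed=(config.seed + i) % (2**31 - 1)
            )
        except RegistrationError as exc:
            raise RegistrationError(f"frame {i}: {exc}") from exc
        warped = apply_affine(moving, params, fill=fill)
        registered[i] = warped
        params_list.append(params)
        fitness_list.append(trace[-1])
        err_before[i] = float(np.mean(np.abs(moving[mask] - fixed_vals)))
        err_after[i] = float(np.mean(np.abs(warped[mask] - fixed_vals)))
        prev = params
    reg_seq = ThermalSequence(
        frames=registered, fps=sequence.fps, subject_id=sequence.subject_id
    )
    return reg_seq, RegistrationResult(params_list, fitness_list, err_before, err_after)
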