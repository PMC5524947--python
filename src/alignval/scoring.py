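"""Per-particle alignment precision/accuracy scores and the global Q value.

The statistics implemented here quantify, for every experimental particle
image, how trustworthy its angular assignment is relative to the map being
validated:

* **Clusterability** ``alpha_m`` — the similarity-weighted mean pairwise
  geodesic distance among the directions of the particle's top-xi most
  similar map projections.  A tight cluster (small alpha) means the particle
  can be oriented *precisely*; a spread set means it cannot.
* **Accuracy statistic** ``chi_m`` — the similarity-weighted mean geodesic
  distance between the particle's previously refined direction and those same
  top-xi match directions.  Small chi means the global search agrees with the
  refinement, i.e. the assignment is *accurate*.

Both raw statistics are hard to interpret in isolation, so each is mapped
through the unique straight line sending a Monte-Carlo *noise* reference
(random orientations in the asymmetric unit, averaged over M repeats) to 0
and a *perfect* reference (the map projected at the particle's own recorded
orientation, with its CTF, no noise, pushed through the identical global
search) to 1.  Scores are reported unclamped; values beyond [0, 1] are
meaningful and expected occasionally.

The global indicator is ``Q``: the percentage of particles whose precision
and accuracy scores both reach the threshold (default 0.5, the midpoint
between the two references).  Pruning keeps exactly those particles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from . import imageops
from .geometry import (
    Orientation,
    SymmetryGroup,
    direction_to_euler,
    geodesic_distance,
    geodesic_distance_matrix,
    random_directions_in_au,
    sample_projection_grid,
)
from .imageops import MapVolume, MatchSet, ParticleImage

logger = logging.getLogger("alignval")

__all__ = [
    "DegenerateReferenceError",
    "ReferenceStats",
    "ParticleScores",
    "ValidationParams",
    "ValidationReport",
    "clusterability_alpha",
    "noise_alpha_reference",
    "accuracy_chi",
    "noise_chi_reference",
    "precision_score",
    "accuracy_score",
    "q_value",
    "validate_particles",
    "prune",
]


class DegenerateReferenceError(ValueError):
    """Good and noise references coincide; the linear score map is undefined."""


@dataclass(frozen=True)
class ReferenceStats:
    """Monte-Carlo noise calibration values (radians)."""

    alpha_noise_hat: float
    chi_noise_hat: float | None
    M: int
    seed: int


@dataclass
class ParticleScores:
    """Raw statistics and quality scores for one particle.

    ``q_p``/``q_a`` are the precision/accuracy scores (1 = like the perfect
    reference, 0 = like pure noise, unclamped).  ``flags`` collects
    ``degenerate-reference`` / ``missing-orientation`` conditions; a flagged
    particle counts as failing at any threshold.
    """

    index: int
    alpha: float = np.nan
    alpha_good: float = np.nan
    chi: float | None = None
    chi_good: float | None = None
    q_p: float | None = None
    q_a: float | None = None
    flags: tuple[str, ...] = ()

    def passes(self, tau: float, require_accuracy: bool = True) -> bool:
        if self.flags:
            return False
        if self.q_p is None or not self.q_p >= tau:
            return False
        if require_accuracy:
            return self.q_a is not None and self.q_a >= tau
        return True


@dataclass(frozen=True)
class ValidationParams:
    """Run parameters; defaults follow standard practice for this method."""

    xi: int = 7
    delta: float = 5.0
    M: int = 500
    tau: float = 0.5
    rot_step: float | None = None  # defaults to delta
    max_shift: float | None = None  # defaults to box/8
    sym: str = "C1"
    seed: int = 0
    mode: str = "full"  # "full" | "precision"
    mask_radius: float | None = None

    def resolved(self, box_size: int) -> "ValidationParams":
        return replace(
            self,
            rot_step=self.rot_step if self.rot_step is not None else self.delta,
            max_shift=self.max_shift if self.max_shift is not None else box_size // 8,
        )


@dataclass
class ValidationReport:
    """Per-particle scores plus the global summary of one validation run."""

    scores: list[ParticleScores]
    Q: float
    percent_precise: float
    percent_accurate: float | None
    mean_q_p: float
    mean_q_a: float | None
    references: ReferenceStats
    params: ValidationParams
    grid_size: int = 0

    @property
    def n_particles(self) -> int:
        return len(self.scores)

    def to_dataframe(self):
        import pandas as pd

        rows = [
            {
                "particle": s.index,
                "alpha": s.alpha,
                "alpha_good": s.alpha_good,
                "chi": s.chi,
                "chi_good": s.chi_good,
                "q_p": s.q_p,
                "q_a": s.q_a,
                "flags": ";".join(s.flags),
            }
            for s in self.scores
        ]
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# raw statistics


def clusterability_alpha(ms: MatchSet, sym: SymmetryGroup | None = None) -> float:
    """Weighted mean pairwise geodesic distance among the match directions.

    ``alpha = sum_{k != n} w_n w_k d(p_n, p_k) / sum_{k != n} w_n w_k`` with
    ``d`` the symmetry-aware geodesic distance.  Invariant under entry
    permutation and under common positive rescaling of the weights.
    """
    if ms.xi < 2:
        raise ValueError("clusterability needs at least 2 matches")
    w = ms.weights
    dmat = geodesic_distance_matrix(ms.directions, sym)
    ww = np.outer(w, w)
    np.fill_diagonal(ww, 0.0)
    denom = ww.sum()
    if abs(denom) < 1e-300:
        raise DegenerateReferenceError("all pairwise weight products vanish")
    return float((ww * dmat).sum() / denom)


def noise_alpha_reference(
    xi: int,
    M: int,
    sym: SymmetryGroup | None = None,
    seed: int | np.random.Generator = 0,
    return_samples: bool = False,
):
    """Mean clusterability of ``xi`` uniform random asymmetric-unit directions.

    Models the worst case — every orientation equally likely — by drawing
    ``xi`` directions uniformly in the asymmetric unit with unit weights and
    averaging the clusterability over ``M`` independent repeats.
    """
    if xi < 2 or M < 1:
        raise ValueError("need xi >= 2 and M >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    dirs = random_directions_in_au(M * xi, sym, rng).reshape(M, xi, 3)
    if sym is None or sym.order == 1:
        dots = np.einsum("mik,mjk->mij", dirs, dirs)
        d = np.arccos(np.clip(dots, -1.0, 1.0))
    else:
        orb = np.einsum("gab,mjb->mjga", sym.matrices, dirs)  # (M, xi, |G|, 3)
        dots = np.einsum("mia,mjga->mijg", dirs, orb)
        d = np.min(np.arccos(np.clip(dots, -1.0, 1.0)), axis=-1)
    mask = ~np.eye(xi, dtype=bool)
    samples = d[:, mask].mean(axis=1)  # unit weights: plain mean over ordered pairs
    return (samples.mean(), samples) if return_samples else float(samples.mean())


def accuracy_chi(p_hat: np.ndarray, ms: MatchSet, sym: SymmetryGroup | None = None) -> float:
    """Weighted mean geodesic distance from the recorded direction to the matches.

    ``chi = sum_k w_k d(p_hat, p_k) / sum_k w_k``; in [0, pi].
    """
    w = ms.weights
    wsum = w.sum()
    if abs(wsum) < 1e-300:
        raise DegenerateReferenceError("zero weight sum")
    d = geodesic_distance(np.asarray(p_hat, dtype=float), ms.directions, sym)
    return float((w * d).sum() / wsum)


def noise_chi_reference(
    p_hat: np.ndarray,
    xi: int,
    M: int,
    sym: SymmetryGroup | None = None,
    seed: int | np.random.Generator = 0,
    return_samples: bool = False,
):
    """Mean accuracy statistic of the recorded direction vs random directions.

    Unit-weight mean distance from ``p_hat`` to ``xi`` uniform asymmetric-unit
    directions, averaged over ``M`` repeats.  Computed at the particle's own
    ``p_hat`` because for non-trivial symmetry the distance-to-uniform
    distribution depends on where in the asymmetric unit the particle sits
    (for C1 it collapses to a constant pi/2 in expectation).
    """
    if xi < 1 or M < 1:
        raise ValueError("need xi >= 1 and M >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    dirs = random_directions_in_au(M * xi, sym, rng).reshape(M, xi, 3)
    d = geodesic_distance(np.asarray(p_hat, dtype=float)[None, None, :], dirs, sym)
    samples = d.mean(axis=1)
    return (samples.mean(), samples) if return_samples else float(samples.mean())


# ---------------------------------------------------------------------------
# score mappings


def _linear_score(x: float, x_good: float, x_noise: float) -> float:
    if abs(x_good - x_noise) < 1e-9:
        raise DegenerateReferenceError("good and noise references coincide")
    return float((x - x_noise) / (x_good - x_noise))


def precision_score(alpha_m: float, alpha_good: float, alpha_noise: float) -> float:
    """Linear map sending the noise reference to 0 and the perfect reference to 1.

    Evaluated at ``alpha_m``; not clamped, so values outside [0, 1] are
    possible and reported as-is.
    """
    return _linear_score(alpha_m, alpha_good, alpha_noise)


def accuracy_score(chi_m: float, chi_good: float, chi_noise: float) -> float:
    """Same two-point linear map for the accuracy statistic."""
    return _linear_score(chi_m, chi_good, chi_noise)


def q_value(scores: list[ParticleScores], tau: float = 0.5) -> float:
    """Percentage of particles passing both precision and accuracy at ``tau``.

    Flagged (degenerate / missing-orientation) particles count as failing.
    """
    if not scores:
        raise ValueError("empty score list")
    npass = sum(s.passes(tau) for s in scores)
    return 100.0 * npass / len(scores)


def prune(report: ValidationReport, tau: float | None = None) -> np.ndarray:
    """Indices of particles passing the score threshold.

    In full mode both scores must reach ``tau``; in precision-only mode just
    the precision score.  At the report's own tau the selection size matches
    its Q exactly.
    """
    if tau is None:
        tau = report.params.tau
    require_acc = report.params.mode == "full"
    return np.array(
        [s.index for s in report.scores if s.passes(tau, require_accuracy=require_acc)],
        dtype=int,
    )


# ---------------------------------------------------------------------------
# pipeline


def _as_array_stack(images) -> np.ndarray:
    if isinstance(images, np.ndarray):
        return images.astype(np.float64, copy=False)
    return np.stack([im.data if isinstance(im, ParticleImage) else np.asarray(im) for im in images])


def validate_particles(vol: MapVolume, images, records, params: ValidationParams | None = None) -> ValidationReport:
    """Run the full per-particle validation pipeline and assemble the report.

    For each particle: (i) a global in-plane + angular search against CTF-
    matched grid projections of the map yields the top-xi match set, hence
    ``alpha_m`` and (full mode) ``chi_m``; (ii) the particle's *perfect*
    counterpart — the map projected at its recorded orientation and shift,
    distorted by its own CTF, no noise — goes through the identical,
    independent search, yielding ``alpha_good`` / ``chi_good``; (iii) the raw
    statistics are mapped to scores using a shared Monte-Carlo noise
    clusterability reference and a per-particle noise accuracy reference.

    ``records`` must provide ``.orientation`` (an :class:`Orientation`, or
    None in precision-only mode) and ``.ctf`` (a :class:`CTFParams` or None)
    per particle.  In precision-only mode the perfect counterpart is built at
    the particle's rank-1 match orientation, since no refined orientation
    exists yet.
    """
    if params is None:
        params = ValidationParams()
    stack = _as_array_stack(images)
    n_particles = len(stack)
    if n_particles == 0:
        raise ValueError("empty particle stack")
    if stack.shape[-1] != vol.box_size or stack.shape[-2] != vol.box_size:
        raise ValueError(
            f"particle box {stack.shape[-2:]} does not match map box {vol.box_size}"
        )
    if len(records) != n_particles:
        raise ValueError(f"{len(records)} metadata records for {n_particles} images")
    for rec in records:
        ps = getattr(rec, "pixel_size", None)
        if ps is not None and abs(ps - vol.voxel_size) > 1e-6:
            raise ValueError("particle pixel size does not match map voxel size")
    p = params.resolved(vol.box_size)
    full_mode = p.mode == "full"
    if full_mode:
        for m, rec in enumerate(records):
            if rec.orientation is None:
                raise ValueError(
                    f"particle {m} has no orientation; required in full mode "
                    "(use precision-only mode otherwise)"
                )

    sym = SymmetryGroup(p.sym)
    grid = sample_projection_grid(p.delta, sym)
    refs_raw = imageops.project_directions(vol, grid.eulers)
    logger.info("projection grid: %d directions at delta=%.3g deg (%s)", len(grid), p.delta, p.sym)

    alpha_noise = noise_alpha_reference(p.xi, p.M, sym, np.random.default_rng([p.seed, 0xA1]))
    chi_noise_mean = [] if full_mode else None

    # tiny LRU: the experimental and perfect searches of one particle share a
    # CTF, and identity-CTF runs share one entry; unbounded caching of
    # per-particle defoci would hold the whole reference stack per particle
    from collections import OrderedDict

    prepared_cache: OrderedDict = OrderedDict()

    def prepared_for(ctf):
        key = ctf  # CTFParams is frozen/hashable; None = no CTF
        if key not in prepared_cache:
            refs = (
                refs_raw
                if ctf is None
                else imageops.apply_ctf(refs_raw, ctf, vol.voxel_size)
            )
            prepared_cache[key] = imageops.prepare_references(refs, p.mask_radius)
            while len(prepared_cache) > 4:
                prepared_cache.popitem(last=False)
        else:
            prepared_cache.move_to_end(key)
        return prepared_cache[key]

    def search(img, ctf, index):
        return imageops.global_search(
            img,
            None,
            grid.directions,
            xi=p.xi,
            rot_step=p.rot_step,
            max_shift=p.max_shift,
            mask_radius=p.mask_radius,
            particle_index=index,
            prepared=prepared_for(ctf),
        )

    scores: list[ParticleScores] = []
    running_pass = 0
    for m in range(n_particles):
        rec = records[m]
        ctf = getattr(rec, "ctf", None)
        ms = search(stack[m], ctf, m)
        if logger.isEnabledFor(logging.DEBUG):
            logger.debug(
                "particle %d match set: grid %s ncc %s",
                m,
                ms.grid_indices.tolist(),
                np.round(ms.weights, 4).tolist(),
            )
        s = ParticleScores(index=m)
        flags: list[str] = []
        try:
            s.alpha = clusterability_alpha(ms, sym)
        except DegenerateReferenceError:
            flags.append("degenerate-input")

        if full_mode:
            o = rec.orientation
            p_hat = o.direction()
        else:
            rot, tilt = direction_to_euler(ms.directions[0])
            o = Orientation(
                rot=rot,
                tilt=tilt,
                psi=ms.psis[0],
                shift_x=ms.shifts[0][0],
                shift_y=ms.shifts[0][1],
            )
            p_hat = None

        perfect = imageops.apply_ctf(
            imageops.project_volume(vol, o).data, ctf, vol.voxel_size
        )
        ms_good = search(perfect, ctf, m)
        s.alpha_good = clusterability_alpha(ms_good, sym)
        try:
            s.q_p = precision_score(s.alpha, s.alpha_good, alpha_noise)
        except DegenerateReferenceError:
            flags.append("degenerate-reference")

        if full_mode:
            s.chi = accuracy_chi(p_hat, ms, sym)
            s.chi_good = accuracy_chi(p_hat, ms_good, sym)
            chi_noise = noise_chi_reference(
                p_hat, p.xi, p.M, sym, np.random.default_rng([p.seed, 0xC4, m])
            )
            chi_noise_mean.append(chi_noise)
            try:
                s.q_a = accuracy_score(s.chi, s.chi_good, chi_noise)
            except DegenerateReferenceError:
                if "degenerate-reference" not in flags:
                    flags.append("degenerate-reference")
        s.flags = tuple(flags)
        scores.append(s)
        running_pass += s.passes(p.tau, require_accuracy=full_mode)
        if (m + 1) % 100 == 0:
            logger.info(
                "processed %d/%d particles, running pass rate %.1f%%",
                m + 1,
                n_particles,
                100.0 * running_pass / (m + 1),
            )

    qp_vals = np.array([s.q_p if s.q_p is not None else np.nan for s in scores])
    percent_precise = 100.0 * np.mean(
        [(s.q_p is not None and not s.flags and s.q_p >= p.tau) for s in scores]
    )
    if full_mode:
        qa_vals = np.array([s.q_a if s.q_a is not None else np.nan for s in scores])
        percent_accurate = 100.0 * np.mean(
            [(s.q_a is not None and not s.flags and s.q_a >= p.tau) for s in scores]
        )
        q = q_value(scores, p.tau)
        mean_q_a = float(np.nanmean(qa_vals)) if np.any(np.isfinite(qa_vals)) else np.nan
        chi_noise_ref = float(np.mean(chi_noise_mean))
    else:
        percent_accurate = None
        mean_q_a = None
        chi_noise_ref = None
        q = percent_precise

    return ValidationReport(
        scores=scores,
        Q=q,
        percent_precise=percent_precise,
        percent_accurate=percent_accurate,
        mean_q_p=float(np.nanmean(qp_vals)) if np.any(np.isfinite(qp_vals)) else np.nan,
        mean_q_a=mean_q_a,
        references=ReferenceStats(
            alpha_noise_hat=alpha_noise, chi_noise_hat=chi_noise_ref, M=p.M, seed=p.seed
        ),
        params=p,
        grid_size=len(grid),
    )
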