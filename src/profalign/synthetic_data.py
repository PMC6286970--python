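"""Synthetic structure-profile generators with known ground truth.

Real predictor tracks alternate between positive runs (stems / paired
regions) and negative runs (loops, linkers / unpaired regions).  The
generator emulates that texture with a two-state Markov segment process:
segment lengths are geometric, paired segments draw scores from a positive
band and unpaired segments from the mirrored negative band.

On top of the background generator the module provides motif embedding
(ground-truth coordinates for localization benchmarks), a divergence model
(Gaussian score noise plus sign flips -- "same segmentation, perturbed
scores", the profile-space analogue of sequences that diverge while keeping
their structure), and a reference/positive/negative benchmark builder
emulating a reverse-engineering experiment: positives share the motif's
structure with perturbed scores, negatives are shuffles of the motif.

Every generator is fully deterministic under its seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .profile_io import StructureProfile, shuffle_profile

__all__ = [
    "SyntheticInstance",
    "BenchmarkSet",
    "gen_profile",
    "embed_motif",
    "perturb_profile",
    "make_benchmark",
    "SCORE_BAND_MEAN",
    "SCORE_BAND_SD",
    "SCORE_CLIP",
]

#: Mean magnitude of the paired/unpaired score bands (score units).
SCORE_BAND_MEAN = 0.5
#: Standard deviation of the band magnitude.
SCORE_BAND_SD = 0.25
#: Scores are clipped to [-SCORE_CLIP, +SCORE_CLIP].
SCORE_CLIP = 2.0
#: Floor on the score magnitude so the sign always encodes the state.
_MAG_FLOOR = 0.01


@dataclass(frozen=True)
class SyntheticInstance:
    """A background profile with a motif embedded at a known location.

    ``profile`` is the background with the motif's scores written over
    positions ``[insert_position, insert_position + len(motif) - 1]``
    (1-based inclusive); ``background`` is kept unmodified so tests can
    verify that positions outside the truth interval are untouched.
    """

    background: StructureProfile
    motif: StructureProfile
    profile: StructureProfile
    insert_position: int
    noise_sd: float = 0.0
    flip_fraction: float = 0.0
    seed: int = 0

    @property
    def truth_interval(self) -> tuple[int, int]:
        """1-based inclusive reference interval of the embedded motif."""
        return (self.insert_position, self.insert_position + len(self.motif) - 1)


def gen_profile(
    length: int,
    stem_density: float = 0.5,
    mean_stem_len: float = 8.0,
    seed: int = 0,
    id: str | None = None,
) -> StructureProfile:
    """Generate a random structured profile.

    A two-state (paired/unpaired) segment process with geometric segment
    lengths; paired segments have mean length ``mean_stem_len`` and the
    unpaired mean is set so the stationary paired fraction equals
    ``stem_density``.  Paired positions get ``+|N(0.5, 0.25)|`` scores
    (clipped to magnitude [0.01, 2]), unpaired positions the mirrored
    negative value, so the positive fraction equals the paired fraction
    exactly.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    if not 0.0 <= stem_density <= 1.0:
        raise ValueError(f"stem_density must be in [0, 1], got {stem_density}")
    if mean_stem_len <= 0:
        raise ValueError("mean_stem_len must be positive")
    rng = np.random.default_rng(seed)

    if stem_density == 0.0:
        paired = np.zeros(length, dtype=bool)
    elif stem_density == 1.0:
        paired = np.ones(length, dtype=bool)
    else:
        mean_unpaired = mean_stem_len * (1.0 - stem_density) / stem_density
        paired = np.empty(length, dtype=bool)
        state = bool(rng.random() < stem_density)
        pos = 0
        while pos < length:
            mean = mean_stem_len if state else mean_unpaired
            seg = int(rng.geometric(min(1.0, 1.0 / mean)))
            end = min(pos + seg, length)
            paired[pos:end] = state
            pos = end
            state = not state

    mag = np.clip(np.abs(rng.normal(SCORE_BAND_MEAN, SCORE_BAND_SD, length)),
                  _MAG_FLOOR, SCORE_CLIP)
    scores = np.where(paired, mag, -mag)
    return StructureProfile(
        id=id or f"synthetic_{seed}", scores=scores, source="synthetic"
    )


def embed_motif(
    background: StructureProfile,
    motif: StructureProfile,
    position: int | None = None,
    seed: int = 0,
) -> SyntheticInstance:
    """Overwrite background scores with the motif at a (1-based) position.

    When ``position`` is None a uniformly random admissible start is drawn
    from ``seed``.  The motif must fit entirely inside the background.
    """
    max_start = len(background) - len(motif) + 1
    if max_start < 1:
        raise ValueError(
            f"motif of length {len(motif)} does not fit in background of "
            f"length {len(background)}"
        )
    if position is None:
        position = int(np.random.default_rng(seed).integers(1, max_start + 1))
    if not 1 <= position <= max_start:
        raise ValueError(
            f"motif at position {position} overflows the background "
            f"(admissible starts: 1..{max_start})"
        )
    scores = background.scores.copy()
    scores[position - 1: position - 1 + len(motif)] = motif.scores
    embedded = StructureProfile(
        id=f"{background.id}|embed({motif.id}@{position})",
        scores=scores,
        source="synthetic",
    )
    return SyntheticInstance(
        background=background, motif=motif, profile=embedded,
        insert_position=position, seed=seed,
    )


def perturb_profile(
    p: StructureProfile,
    noise_sd: float = 0.0,
    flip_fraction: float = 0.0,
    seed: int = 0,
) -> StructureProfile:
    """Divergence model: Gaussian score noise, then seeded sign flips.

    Adds zero-mean Gaussian noise (sd ``noise_sd``) per position, then
    multiplies a random subset of ``round(flip_fraction * N)`` positions by
    -1.  Length is preserved; noise 0 / flip 0 is the identity.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if not 0.0 <= flip_fraction <= 1.0:
        raise ValueError("flip_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    scores = p.scores.copy()
    if noise_sd > 0:
        scores = scores + rng.normal(0.0, noise_sd, len(p))
    n_flip = int(round(flip_fraction * len(p)))
    if n_flip:
        idx = rng.choice(len(p), size=n_flip, replace=False)
        scores[idx] *= -1.0
    return StructureProfile(
        id=f"{p.id}|perturbed", scores=scores, source="synthetic"
    )


@dataclass(frozen=True)
class BenchmarkSet:
    """Reference / positive / negative profile sets around one true motif."""

    motif: StructureProfile
    references: tuple[StructureProfile, ...]
    positives: tuple[StructureProfile, ...]
    negatives: tuple[StructureProfile, ...]
    noise_sd: float
    seed: int


def make_benchmark(
    motif_len: int = 200,
    n_ref: int = 25,
    n_pos: int = 25,
    n_neg: int = 25,
    noise_sd: float = 0.3,
    seed: int = 0,
    stem_density: float = 0.5,
) -> BenchmarkSet:
    """Build a structure-retrieval benchmark around a single true motif.

    References and positives are independent score perturbations of the
    motif (same underlying segmentation -- structurally alike, numerically
    divergent); negatives are block shuffles of the motif (same score
    composition, scrambled architecture).  The 25/25/25 default mirrors a
    reference/positive/negative reverse-engineering design.
    """
    if min(n_ref, n_pos, n_neg) < 1:
        raise ValueError("all set sizes must be >= 1")
    rng = np.random.default_rng(seed)
    motif = gen_profile(motif_len, stem_density=stem_density,
                        seed=int(rng.integers(2**31)), id="motif")

    def _perturbed(prefix: str, n: int) -> tuple[StructureProfile, ...]:
        out = []
        for k in range(n):
            prof = perturb_profile(motif, noise_sd=noise_sd, flip_fraction=0.0,
                                   seed=int(rng.integers(2**31)))
            out.append(prof.with_scores(prof.scores, id=f"{prefix}_{k:02d}"))
        return tuple(out)

    references = _perturbed("ref", n_ref)
    positives = _perturbed("pos", n_pos)
    negatives = []
    for k in range(n_neg):
        shuf = shuffle_profile(motif, mode="block", seed=int(rng.integers(2**31)))
        negatives.append(shuf.with_scores(shuf.scores, id=f"neg_{k:02d}"))
    negatives = tuple(negatives)
    return BenchmarkSet(
        motif=motif, references=references, positives=positives,
        negatives=negatives, noise_sd=noise_sd, seed=seed,
    )
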