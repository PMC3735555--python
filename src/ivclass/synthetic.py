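"""Synthetic expression matrices with planted interval structure.

Two signature structures are available:

``shift``
    Signature genes carry class-specific means separated by
    ``effect_size * noise_sd``.  Values are drawn from a clipped normal
    (clip at ``+-clip_z`` sd around the class mean) so that for effect
    sizes of at least ``2 * clip_z`` learned entropy cuts land between
    the class means.
``band``
    Two-class design whose signal lives in narrow expression bands
    (``h = effect_size * noise_sd``): most samples of the first class sit
    in the central band ``(-h, h)`` and most of the second in the two
    flanking bands ``+-(h, 1.9h)``; a small fraction of both classes is a
    diffuse subtype drawn identically from a wide uniform.  Flank side
    and banded/diffuse subtype are drawn once per sample and shared by
    all of its signature genes.  The construction keeps per-gene class
    means equal (fold change ~ 0, mean-based t-tests blind), and because
    the tails are class-identical, the data-driven ``mean +- sd`` ternary
    cuts produce up/normal/down bins holding the same fraction of both
    classes -- the ternary coding is uninformative by construction while
    fine intervals separate the classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import ExpressionMatrix, ValidationError

__all__ = ["SyntheticSpec", "GroundTruth", "generate"]

# band-structure geometry, in units of h = effect_size * noise_sd:
# class 0 occupies the central band (-1, 1) and class 1 the two flanking
# bands +-(1, _B_INNER); a _DIFFUSE_P fraction of BOTH classes is a diffuse
# subtype drawn identically from U(-_DIFFUSE_W, _DIFFUSE_W) in every
# signature gene.  Because the diffuse component is class-identical, the
# data-driven ternary cuts at mean +- sd (which land well outside the
# banded region, ~2.4) produce up/normal/down bins holding both classes
# in equal proportion wherever they fall.
_B_INNER = 1.9
_DIFFUSE_P = 0.15
_DIFFUSE_W = 9.0


@dataclass
class SyntheticSpec:
    n_samples_per_class: int = 40
    n_classes: int = 2
    n_signature_genes: int = 20
    n_noise_genes: int = 480
    structure: str = "shift"
    effect_size: float = 3.0
    noise_sd: float = 1.0
    seed: int = 0
    heavy_tail: bool = False  # t(3)-scaled noise instead of Gaussian
    clip_z: float = 1.4  # shift-signature noise truncation, in sd units

    def __post_init__(self) -> None:
        if min(self.n_samples_per_class, self.n_classes, self.n_signature_genes) < 1:
            raise ValidationError("all counts must be positive")
        if self.n_noise_genes < 0:
            raise ValidationError("n_noise_genes must be >= 0")
        if self.structure not in ("shift", "band"):
            raise ValidationError(f"unknown structure {self.structure!r}")
        if self.structure == "band" and self.n_classes != 2:
            raise ValidationError("band structure is a two-class design")
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be positive")
        if self.effect_size < 0:
            raise ValidationError("effect_size must be >= 0")
        if self.clip_z <= 0:
            raise ValidationError("clip_z must be positive")


@dataclass
class GroundTruth:
    signature_genes: list[str]
    # per gene -> class label -> generating interval(s) as (lo, hi) pairs
    class_intervals: dict[str, dict[str, list[tuple[float, float]]]] = field(default_factory=dict)
    # per gene -> class label -> generating mean (shift structure)
    class_means: dict[str, dict[str, float]] = field(default_factory=dict)


def _noise(rng: np.random.Generator, shape: tuple[int, ...], spec: SyntheticSpec) -> np.ndarray:
    if spec.heavy_tail:
        draw = rng.standard_t(3, size=shape) / np.sqrt(3.0)  # unit variance
    else:
        draw = rng.standard_normal(shape)
    return draw * spec.noise_sd


def generate(spec: SyntheticSpec) -> tuple[ExpressionMatrix, GroundTruth]:
    """Deterministically generate a labelled matrix plus its ground truth."""
    rng = np.random.default_rng(spec.seed)
    K, npc = spec.n_classes, spec.n_samples_per_class
    n = K * npc
    classes = [f"c{k}" for k in range(K)]
    sample_ids = [f"s{j:04d}" for j in range(n)]
    labels = {sample_ids[j]: classes[j // npc] for j in range(n)}
    y = np.repeat(np.arange(K), npc)

    # band structure: flank side and banded/diffuse subtype are
    # per-sample traits shared by all signature genes (a coherent
    # molecular subtype); the sign balance keeps per-gene class means
    # equal
    flank_sign = rng.choice([-1.0, 1.0], size=n)
    diffuse_mode = rng.random(n) < _DIFFUSE_P

    sig_genes = [f"sig{i:04d}" for i in range(spec.n_signature_genes)]
    noise_genes = [f"nse{i:04d}" for i in range(spec.n_noise_genes)]
    gene_ids = sig_genes + noise_genes
    values = np.empty((len(gene_ids), n))
    truth = GroundTruth(signature_genes=list(sig_genes))

    sep = spec.effect_size * spec.noise_sd
    # shift-signature noise is truncated at +-clip_z sd around the class
    # mean so that, for effect sizes >= 2*clip_z, every class-boundary
    # midpoint (and hence every entropy cut) lies between the class means
    clip = spec.clip_z * spec.noise_sd
    for i, g in enumerate(sig_genes):
        if spec.structure == "shift":
            active = i % K  # this gene's up-shifted class
            mu = np.where(y == active, sep, 0.0)
            raw = np.clip(_noise(rng, (n,), spec), -clip, clip)
            values[i] = mu + raw
            truth.class_means[g] = {
                classes[k]: (sep if k == active else 0.0) for k in range(K)
            }
            truth.class_intervals[g] = {
                classes[k]: [
                    ((sep - clip, sep + clip) if k == active else (-clip, clip))
                ]
                for k in range(K)
            }
        else:  # band
            h = sep
            inner0 = rng.uniform(-h, h, size=n)
            inner1 = rng.uniform(h, _B_INNER * h, size=n) * flank_sign
            diffuse = rng.uniform(-_DIFFUSE_W * h, _DIFFUSE_W * h, size=n)
            banded = np.where(y == 0, inner0, inner1)
            values[i] = np.where(diffuse_mode, diffuse, banded)
            truth.class_means[g] = {classes[0]: 0.0, classes[1]: 0.0}
            truth.class_intervals[g] = {
                classes[0]: [(-h, h)],
                classes[1]: [(-_B_INNER * h, -h), (h, _B_INNER * h)],
            }
    for i in range(spec.n_noise_genes):
        values[spec.n_signature_genes + i] = _noise(rng, (n,), spec)

    matrix = ExpressionMatrix(gene_ids, sample_ids, values, labels)
    return matrix, truth
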