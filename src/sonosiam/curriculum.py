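"""Three-stage curriculum pair generation.

Pair construction drives what a Siamese network can learn. With condition and
acquisition source confounded, naive random pairing lets the encoder separate
classes by source artifacts alone. The curriculum schedules pair difficulty:

* EASY (early): pairs are drawn within a source tag (or, for dissimilar
  pairs, as plain normal-vs-abnormal contrasts when no single source holds
  both conditions), teaching intra-class similarity without domain noise;
* MEDIUM (mid): similar (same-condition) pairs are drawn across different
  source tags, explicitly pulling cross-source embeddings together (falling
  back to unrestricted same-condition pairs when no condition class spans
  both sources, as in a fully confounded manifest);
* HARD (late): dissimilar pairs share the body part and differ only in
  condition, forcing attention onto the pathology itself.

Similarity labels always follow the condition: y = 1 iff both members share
the condition class.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import numpy as np
import pandas as pd

__all__ = [
    "CurriculumStage",
    "ImagePair",
    "stage_schedule",
    "sample_pairs",
    "sample_random_pairs",
    "pairs_to_frame",
]


class CurriculumStage(IntEnum):
    EASY = 0
    MEDIUM = 1
    HARD = 2


@dataclass
class ImagePair:
    id_a: str
    id_b: str
    y: int  # 1 = similar (same condition), 0 = dissimilar
    stage: CurriculumStage | None = None

    def __post_init__(self):
        if self.id_a == self.id_b:
            raise ValueError("a pair must consist of two distinct images")
        if self.y not in (0, 1):
            raise ValueError("similarity label must be 0 or 1")


def stage_schedule(epoch: int, total_epochs: int,
                   boundaries: tuple = (1 / 3, 2 / 3)) -> CurriculumStage:
    """EASY while epoch/total < b1, MEDIUM while < b2, then HARD."""
    b1, b2 = boundaries
    if not 0.0 < b1 < b2 < 1.0:
        raise ValueError("boundaries must satisfy 0 < b1 < b2 < 1")
    if not 0 <= epoch < total_epochs:
        raise ValueError("epoch must lie in [0, total_epochs)")
    frac = epoch / total_epochs
    if frac < b1:
        return CurriculumStage.EASY
    if frac < b2:
        return CurriculumStage.MEDIUM
    return CurriculumStage.HARD


def _strata(manifest: pd.DataFrame) -> dict:
    idx = {}
    conds = manifest["condition"].to_numpy()
    srcs = manifest["source_tag"].to_numpy()
    parts = manifest["body_part"].to_numpy()
    ids = manifest["id"].to_numpy()
    return {"ids": ids, "cond": conds, "src": srcs, "part": parts}


def _pick2(rng, pool_a: np.ndarray, pool_b: np.ndarray):
    """Two distinct indices, one from each pool (pools may overlap)."""
    for _ in range(64):
        a = int(rng.choice(pool_a))
        b = int(rng.choice(pool_b))
        if a != b:
            return a, b
    raise ValueError("could not draw two distinct members")


def sample_pairs(manifest: pd.DataFrame, stage: CurriculumStage, n_pairs: int,
                 seed: int = 0) -> list[ImagePair]:
    """Draw ``n_pairs`` pairs satisfying the stage constraint, with a balanced
    similar/dissimilar mix (50/50, +-1).

    Raises ``ValueError`` naming the missing stratum when the manifest cannot
    satisfy the stage (e.g. MEDIUM without both source tags in a condition).
    """
    stage = CurriculumStage(stage)
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    m = _strata(manifest)
    rng = np.random.default_rng(seed)
    conds, srcs, parts, ids = m["cond"], m["src"], m["part"], m["ids"]
    n = len(ids)
    all_idx = np.arange(n)
    if len(np.unique(conds)) < 2:
        raise ValueError("manifest must contain both condition classes")

    def stratum(**kw):
        mask = np.ones(n, dtype=bool)
        if "cond" in kw:
            mask &= conds == kw["cond"]
        if "src" in kw:
            mask &= srcs == kw["src"]
        if "part" in kw:
            mask &= parts == kw["part"]
        return all_idx[mask]

    uniq_src = np.unique(srcs)
    uniq_cond = np.unique(conds)
    uniq_part = np.unique(parts)

    # stage preconditions
    if stage == CurriculumStage.MEDIUM and len(uniq_src) < 2:
        raise ValueError(
            "MEDIUM stage needs both source tags in the manifest; "
            "missing stratum: second source tag"
        )
    if stage == CurriculumStage.HARD and not any(
        all(((parts == p) & (conds == c)).any() for c in uniq_cond)
        for p in uniq_part
    ):
        raise ValueError(
            "HARD stage needs a body part with both conditions; "
            "missing stratum: same-body-part cross-condition"
        )

    def draw_similar():
        if stage == CurriculumStage.MEDIUM:
            # same condition, different source tags; fall back to an
            # unrestricted same-condition pair when no class spans both tags
            opts = [
                c for c in uniq_cond
                if all(len(stratum(cond=c, src=s)) > 0 for s in uniq_src)
            ]
            if opts:
                c = rng.choice(opts)
                sa, sb = rng.permutation(uniq_src)[:2]
                a, b = _pick2(rng, stratum(cond=c, src=sa), stratum(cond=c, src=sb))
            else:
                c = rng.choice([c for c in uniq_cond if len(stratum(cond=c)) >= 2])
                pool = stratum(cond=c)
                a, b = _pick2(rng, pool, pool)
        elif stage == CurriculumStage.EASY:
            # same condition AND same source
            opts = [
                (c, s) for c in uniq_cond for s in uniq_src
                if len(stratum(cond=c, src=s)) >= 2
            ]
            if not opts:
                raise ValueError(
                    "EASY stage needs >= 2 images in some (condition, source) "
                    "stratum; missing stratum: same-source same-condition"
                )
            c, s = opts[rng.integers(len(opts))]
            pool = stratum(cond=c, src=s)
            a, b = _pick2(rng, pool, pool)
        else:  # HARD: similar pairs unrestricted beyond same condition
            opts = [c for c in uniq_cond if len(stratum(cond=c)) >= 2]
            if not opts:
                raise ValueError("no condition class with >= 2 images")
            c = rng.choice(opts)
            pool = stratum(cond=c)
            a, b = _pick2(rng, pool, pool)
        return a, b

    def draw_dissimilar():
        if stage == CurriculumStage.EASY:
            # prefer same-source cross-condition; otherwise a plain
            # normal-vs-abnormal contrast (the "obviously distinct" branch)
            opts = [
                s for s in uniq_src
                if all(len(stratum(cond=c, src=s)) > 0 for c in uniq_cond)
            ]
            if opts:
                s = rng.choice(opts)
                a, b = _pick2(
                    rng, stratum(cond=uniq_cond[0], src=s),
                    stratum(cond=uniq_cond[1], src=s),
                )
            else:
                a, b = _pick2(
                    rng, stratum(cond=uniq_cond[0]), stratum(cond=uniq_cond[1])
                )
        elif stage == CurriculumStage.HARD:
            opts = [
                p for p in uniq_part
                if all(len(stratum(cond=c, part=p)) > 0 for c in uniq_cond)
            ]
            if not opts:
                raise ValueError(
                    "HARD stage needs a body part with both conditions; "
                    "missing stratum: same-body-part cross-condition"
                )
            p = rng.choice(opts)
            a, b = _pick2(
                rng, stratum(cond=uniq_cond[0], part=p), stratum(cond=uniq_cond[1], part=p)
            )
        else:  # MEDIUM: dissimilar pairs unconstrained (cross-condition)
            a, b = _pick2(rng, stratum(cond=uniq_cond[0]), stratum(cond=uniq_cond[1]))
        return a, b

    # similar pairs need two distinct same-class members (EASY additionally
    # within one source stratum); when unattainable the whole batch is
    # dissimilar, as with a forced two-image manifest
    if stage == CurriculumStage.EASY:
        can_sim = any(
            ((conds == c) & (srcs == s)).sum() >= 2
            for c in uniq_cond for s in uniq_src
        )
    else:
        can_sim = any((conds == c).sum() >= 2 for c in uniq_cond)
    n_sim = (n_pairs + 1) // 2 if can_sim else 0
    pairs = []
    for i in range(n_pairs):
        if i < n_sim:
            a, b = draw_similar()
        else:
            a, b = draw_dissimilar()
        y = int(conds[a] == conds[b])
        pairs.append(ImagePair(str(ids[a]), str(ids[b]), y, stage))
    order = rng.permutation(n_pairs)
    return [pairs[i] for i in order]


def sample_random_pairs(manifest: pd.DataFrame, n_pairs: int, seed: int = 0,
                        balanced: bool = True) -> list[ImagePair]:
    """Naive pairing baseline: no stage constraints.

    ``balanced`` keeps the 50/50 similar/dissimilar mix (so the comparison
    with the curriculum isolates the stratum structure, not label balance).
    """
    m = _strata(manifest)
    rng = np.random.default_rng(seed)
    conds, ids = m["cond"], m["ids"]
    n = len(ids)
    all_idx = np.arange(n)
    uniq_cond = np.unique(conds)
    pairs = []
    n_sim = (n_pairs + 1) // 2
    for i in range(n_pairs):
        if balanced:
            if i < n_sim:
                c = rng.choice([c for c in uniq_cond if (conds == c).sum() >= 2])
                pool = all_idx[conds == c]
                a, b = _pick2(rng, pool, pool)
            else:
                a, b = _pick2(
                    rng, all_idx[conds == uniq_cond[0]], all_idx[conds == uniq_cond[1]]
                )
        else:
            a, b = _pick2(rng, all_idx, all_idx)
        pairs.append(ImagePair(str(ids[a]), str(ids[b]), int(conds[a] == conds[b]), None))
    order = rng.permutation(n_pairs)
    return [pairs[i] for i in order]


def pairs_to_frame(pairs: list[ImagePair]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "id_a": [p.id_a for p in pairs],
            "id_b": [p.id_b for p in pairs],
            "y": [p.y for p in pairs],
            "stage": [p.stage.name if p.stage is not None else "RANDOM" for p in pairs],
        }
    )
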