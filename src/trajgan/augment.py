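"""Tenfold expansion of replicate groups by pairwise linear interpolation.

Each (region, condition) group of n replicates contributes C(n, 2)
unordered pairs; every pair (S1, S2) yields nine augmented profiles
``S_aug = x*S1 + (1 - x)*S2`` for x in 0.1..0.9, so the group grows by
``9 * C(n, 2)`` samples (a group of six gains 135). Interpolation happens
on the log2norm scale, before min-max scaling; since the scaler is a
per-gene affine map, augmenting and scaling commute exactly.

``qc_embedding`` is a quantitative stand-in for visual t-SNE inspection of
the augmented data: it embeds originals plus augmented samples and reports
the fraction of augmented samples whose nearest original neighbor in the
embedding shares their group label.
"""

from __future__ import annotations

import itertools
import logging

import numpy as np
import pandas as pd
from sklearn.manifold import TSNE

from .containers import ExpressionMatrix

logger = logging.getLogger(__name__)

#: The nine interior mixing weights.
DEFAULT_WEIGHTS: tuple[float, ...] = tuple(np.round(np.arange(1, 10) * 0.1, 1))


def _check_weights(weights) -> np.ndarray:
    w = np.asarray(weights, dtype=float)
    if w.ndim != 1 or not ((w > 0) & (w < 1)).all() or not (np.diff(w) > 0).all():
        raise ValueError("weights must be strictly increasing and inside (0, 1)")
    return w


def enumerate_pairs(group_samples: list[str]) -> list[tuple[str, str]]:
    """All unordered sample pairs of a group, in lexicographic order."""
    if len(group_samples) < 2:
        raise ValueError("pair enumeration needs a group of at least 2 samples")
    if len(set(group_samples)) != len(group_samples):
        raise ValueError("duplicate sample ids in group")
    return list(itertools.combinations(sorted(group_samples), 2))


def interpolate_pair(
    s1: pd.Series, s2: pd.Series, weights=DEFAULT_WEIGHTS
) -> pd.DataFrame:
    """Nine convex combinations of two profiles, one column per weight."""
    w = _check_weights(weights)
    if not s1.index.equals(s2.index):
        raise ValueError("profiles must share the same gene set and order")
    v1 = s1.to_numpy()[:, None]
    v2 = s2.to_numpy()[:, None]
    mixed = w[None, :] * v1 + (1.0 - w[None, :]) * v2
    return pd.DataFrame(mixed, index=s1.index, columns=[f"x{x:g}" for x in w])


def augment_dataset(
    expr: ExpressionMatrix,
    groups: dict[tuple[str, str], list[str]],
    weights=DEFAULT_WEIGHTS,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Append ``9 * C(n, 2)`` interpolated samples per group.

    Returns the combined matrix (original columns first, augmented columns
    appended in deterministic group/pair/weight order) and a provenance
    table with one row per augmented sample: aug_sample_id, region,
    condition, source1, source2, x.
    """
    w = _check_weights(weights)
    singletons = [key for key, members in groups.items() if len(members) < 2]
    if singletons:
        raise ValueError(f"groups too small to augment (need >= 2 samples): {singletons}")
    blocks = [expr.data]
    records = []
    for (region, condition), members in groups.items():
        missing = [s for s in members if s not in expr.data.columns]
        if missing:
            raise KeyError(f"group samples absent from matrix: {missing[:5]}")
        for s1, s2 in enumerate_pairs(members):
            mixed = interpolate_pair(expr.data[s1], expr.data[s2], w)
            cols = {}
            for x, col in zip(w, mixed.columns):
                aug_id = f"aug_{s1}+{s2}_x{x:g}"
                cols[aug_id] = mixed[col]
                records.append(
                    {
                        "aug_sample_id": aug_id,
                        "region": region,
                        "condition": condition,
                        "source1": s1,
                        "source2": s2,
                        "x": float(x),
                    }
                )
            blocks.append(pd.DataFrame(cols))
    combined = pd.concat(blocks, axis=1)
    provenance = pd.DataFrame(
        records, columns=["aug_sample_id", "region", "condition", "source1", "source2", "x"]
    )
    return ExpressionMatrix(combined, expr.scale), provenance


def augmented_sample_table(samples: pd.DataFrame, provenance: pd.DataFrame) -> pd.DataFrame:
    """Combined metadata for originals plus augmented samples.

    Columns: sample_id, region, condition, origin ("original"/"augmented").
    """
    orig = samples[["sample_id", "region", "condition"]].copy()
    orig["origin"] = "original"
    aug = provenance.rename(columns={"aug_sample_id": "sample_id"})[
        ["sample_id", "region", "condition"]
    ].copy()
    aug["origin"] = "augmented"
    return pd.concat([orig, aug], ignore_index=True)


def qc_embedding(
    expr: ExpressionMatrix,
    labels: pd.Series,
    original_ids: list[str],
    perplexity: float = 40.0,
    n_iter: int = 7000,
    n_components: int = 2,
    seed: int = 0,
) -> tuple[pd.DataFrame, float]:
    """t-SNE embedding of originals + augmented with a label-agreement score.

    The score is the fraction of augmented samples whose nearest original
    neighbor in the embedding shares their group label; 1.0 vacuously when
    every sample is original or only one label exists. Stochastic — the seed
    is a required part of the record.

    Parameters mirror the common t-SNE settings for this kind of QC
    (perplexity 40, 7000 iterations); the perplexity is reduced with a
    warning when the sample count is too small to support it.
    """
    sample_ids = expr.sample_ids
    missing = [s for s in sample_ids if s not in labels.index]
    if missing:
        raise ValueError(f"labels missing for samples: {missing[:5]}")
    n = len(sample_ids)
    eff_perplexity = perplexity
    if perplexity >= (n - 1) / 3:
        eff_perplexity = max(2.0, (n - 1) / 3 - 1)
        logger.warning(
            "perplexity %.0f too large for %d samples; reduced to %.1f",
            perplexity,
            n,
            eff_perplexity,
        )
    tsne = TSNE(
        n_components=n_components,
        perplexity=eff_perplexity,
        max_iter=max(int(n_iter), 250),
        random_state=seed,
        init="pca",
    )
    coords = tsne.fit_transform(expr.data.to_numpy().T)
    embedding = pd.DataFrame(
        coords,
        index=pd.Index(sample_ids, name="sample_id"),
        columns=[f"dim{i + 1}" for i in range(n_components)],
    )
    embedding["label"] = labels.reindex(sample_ids).to_numpy()

    original_set = set(original_ids)
    augmented = [s for s in sample_ids if s not in original_set]
    if not augmented or labels.reindex(sample_ids).nunique() <= 1:
        return embedding, 1.0
    orig_xy = coords[[sample_ids.index(s) for s in original_ids], :n_components]
    agree = 0
    for s in augmented:
        xy = coords[sample_ids.index(s), :n_components]
        nearest = int(np.argmin(((orig_xy - xy) ** 2).sum(axis=1)))
        if labels[original_ids[nearest]] == labels[s]:
            agree += 1
    return embedding, agree / len(augmented)
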