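"""Enzyme Activity Counts and PRMT scores.

Per-sample read counts for unique enzyme functions become Enzyme
Activity Counts (EAC; default transform log2(count+1)), are made
comparable across samples by quantile normalization (nEAC), and are
turned into Predicted Relative Metabolomic Turnover scores against a
reference profile:

    PRMT_x = -( M . (nEAC_x - nEAC_ref) )

where M is the EMM (metabolites x enzymes). The sign convention makes a
positive score mean relatively greater *consumption* capacity for the
metabolite in sample x (enzymes consuming it carry negative EMM
entries, so a gain in their abundance flips to a positive score); a
negative score means relatively greater accumulation. Scores compare
turnover potential between metagenomes — they are not net fluxes.

Tables are pandas DataFrames with rows = enzyme ids (or metabolite ids
for scores) and columns = sample ids.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TRANSFORMS = ("log2p1", "raw")
SIGN_CONVENTIONS = ("consumption-positive", "production-positive")


def compute_eac(counts: pd.DataFrame, transform: str = "log2p1") -> pd.DataFrame:
    """Transform raw read counts into Enzyme Activity Counts.

    ``log2p1`` maps count -> log2(count+1), keeping heavy-tailed
    abundance tables comparable; ``raw`` keeps counts untouched.
    """
    if transform not in TRANSFORMS:
        raise ValueError(f"unknown transform {transform!r}; expected {TRANSFORMS}")
    values = counts.to_numpy()
    if (values < 0).any():
        bad = counts.lt(0)
        loc = [(i, c) for c in counts.columns for i in counts.index[bad[c]]]
        raise ValueError(f"negative counts at {loc[:5]}")
    if transform == "log2p1":
        eac = pd.DataFrame(
            np.log2(values.astype(float) + 1.0),
            index=counts.index,
            columns=counts.columns,
        )
    else:
        eac = counts.astype(float)
    eac.attrs["transform"] = transform
    return eac


def quantile_normalize(eac: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize EACs across samples (columns).

    The reference distribution is the element-wise mean of each sample's
    descending-sorted value vector: the highest value in every sample
    becomes the mean of the highest values, the second highest the mean
    of the second highest, and so on. Each sample's values are replaced
    by the reference value at their within-sample rank; tied values all
    receive the mean of the reference values spanning the tied ranks.

    After normalization every sample has an identical multiset of
    values (the reference distribution, stored in
    ``result.attrs["reference_distribution"]``). Idempotent.
    """
    if eac.shape[1] < 2:
        raise ValueError(
            "quantile normalization needs >= 2 samples; "
            "skip normalization for a single sample"
        )
    values = eac.to_numpy(dtype=float)
    ref_asc = np.sort(values, axis=0).mean(axis=1)  # ascending reference
    out = np.empty_like(values)
    n = values.shape[0]
    for j in range(values.shape[1]):
        col = values[:, j]
        order = np.argsort(col, kind="mergesort")
        sorted_col = col[order]
        i = 0
        while i < n:
            k = i
            while k < n and sorted_col[k] == sorted_col[i]:
                k += 1
            out[order[i:k], j] = ref_asc[i:k].mean()
            i = k
    neac = pd.DataFrame(out, index=eac.index, columns=eac.columns)
    neac.attrs["reference_distribution"] = ref_asc[::-1].tolist()  # descending
    neac.attrs["transform"] = eac.attrs.get("transform", "unknown")
    return neac


def reference_neac(
    neac: pd.DataFrame,
    samples: list[str] | None = None,
    method: str = "mean-of-neac",
) -> pd.Series:
    """Reference profile: element-wise mean of the (selected) sample vectors."""
    if method != "mean-of-neac":
        raise ValueError(f"unknown reference method {method!r}")
    cols = list(neac.columns) if samples is None else list(samples)
    if not cols:
        raise ValueError("reference requires at least one sample")
    missing = [c for c in cols if c not in neac.columns]
    if missing:
        raise ValueError(f"reference samples not in table: {missing}")
    ref = neac[cols].mean(axis=1)
    ref.name = "reference"
    return ref


def prmt_scores(
    emm: pd.DataFrame,
    neac: pd.DataFrame,
    reference: pd.Series,
    sign_convention: str = "consumption-positive",
) -> pd.DataFrame:
    """Per-metabolite, per-sample turnover scores against a reference.

    Enzyme labels of the EMM and the nEAC table are aligned on their
    intersection (mismatches are logged; enzymes absent from the EMM
    cannot move any score and EMM columns with no counts contribute
    nothing). With the default ``consumption-positive`` convention the
    score is -(M . delta); ``production-positive`` returns +(M . delta).
    """
    if sign_convention not in SIGN_CONVENTIONS:
        raise ValueError(
            f"unknown sign convention {sign_convention!r}; expected {SIGN_CONVENTIONS}"
        )
    common = emm.columns.intersection(neac.index)
    if len(common) == 0:
        raise ValueError("no enzyme labels shared between EMM and nEAC table")
    only_counts = len(neac.index.difference(emm.columns))
    only_emm = len(emm.columns.difference(neac.index))
    if only_counts or only_emm:
        logger.info(
            "enzyme label alignment: %d only in counts, %d only in EMM",
            only_counts,
            only_emm,
        )
    ref = reference.reindex(common)
    if ref.isna().any():
        raise ValueError("reference vector missing aligned enzyme labels")
    delta = neac.loc[common].sub(ref, axis=0)
    scores = emm[common] @ delta
    if sign_convention == "consumption-positive":
        scores = -scores
    scores.attrs["sign_convention"] = sign_convention
    scores.attrs["reference"] = reference.name or "reference"
    return scores
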