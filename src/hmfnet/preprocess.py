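"""Ct normalization, pseudo-reference ranking, imputation, and scaling.

Raw cycle-threshold (Ct) values are normalized against a per-sample
*pseudo reference*: because no single housekeeping gene is stable across
samples, the median Ct over all genes in a sample stands in for a
reference gene.  The resulting -ddCt values are replicate-averaged into
per-strain mean profiles and min-max scaled to [0, 1] for system
identification.

A "sample" throughout is one organ from one animal at one age.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from hmfnet.containers import Profile, ProfileSet

logger = logging.getLogger(__name__)

_SAMPLE_KEYS = ["strain", "organ", "age_weeks", "animal"]


def normalize_ct(ct: pd.DataFrame) -> pd.DataFrame:
    """Normalize raw Ct values to -ddCt expression values.

    Two nested median centerings:

    * dCt = Ct - median over genes within the sample (pseudo reference);
    * ddCt = dCt - median over samples for each (organ, gene).

    The returned ``value`` column is -ddCt, so larger values mean higher
    expression.  Missing Ct entries propagate as missing; samples whose
    genes are all missing are dropped with a warning.
    """
    df = ct.copy()
    required = {"animal", "strain", "organ", "age_weeks", "gene", "Ct"}
    missing_cols = required - set(df.columns)
    if missing_cols:
        raise ValueError(f"Ct table lacks columns: {sorted(missing_cols)}")

    all_missing = df.groupby(_SAMPLE_KEYS)["Ct"].transform(lambda s: s.isna().all())
    if all_missing.any():
        n_drop = df.loc[all_missing, _SAMPLE_KEYS].drop_duplicates().shape[0]
        logger.warning("dropping %d sample(s) with all genes missing", n_drop)
        df = df[~all_missing].copy()

    df["dCt"] = df["Ct"] - df.groupby(_SAMPLE_KEYS)["Ct"].transform("median")
    df["ddCt"] = df["dCt"] - df.groupby(["organ", "gene"])["dCt"].transform("median")
    df["value"] = -df["ddCt"]
    return df[["animal", "strain", "organ", "age_weeks", "gene", "value"]].reset_index(
        drop=True
    )


def rank_pseudo_reference(ct: pd.DataFrame) -> pd.DataFrame:
    """Stability ranking of the per-sample median against single genes.

    For every (organ, age) cell with at least two samples, each candidate
    reference — every single gene, plus the per-sample median over genes —
    is scored by its standard deviation across the cell's samples (lower
    is more stable).  Returns a tidy table with columns (organ, age_weeks,
    candidate, score, rank); the candidate named ``"<median>"`` is the
    pseudo reference.  Ties share the lowest rank.
    """
    rows = []
    for (organ, age), cell in ct.groupby(["organ", "age_weeks"]):
        wide = cell.pivot_table(
            index="animal", columns="gene", values="Ct", aggfunc="mean"
        )
        if wide.shape[0] < 2:
            logger.warning("skipping %s at %s weeks: fewer than 2 samples", organ, age)
            continue
        scores = wide.std(axis=0, ddof=1)
        median_score = wide.median(axis=1).std(ddof=1)
        cand = scores.to_dict()
        cand["<median>"] = median_score
        ser = pd.Series(cand)
        ranks = ser.rank(method="min")
        for name in ser.index:
            rows.append(
                {
                    "organ": organ,
                    "age_weeks": age,
                    "candidate": name,
                    "score": ser[name],
                    "rank": int(ranks[name]),
                }
            )
    return pd.DataFrame(rows)


def impute_missing(expr: pd.DataFrame, k: int = 10) -> pd.DataFrame:
    """K-nearest-sample imputation of missing expression values.

    Each missing (sample, gene) entry is replaced by the mean of that gene
    over the k samples nearest in Euclidean distance, computed over the
    genes both samples have observed.  Neighborhoods are restricted to the
    sample's organ, since organs are normalized independently.  Candidate
    neighbors must have the target gene observed; if fewer than k exist,
    all available are used with a warning.  Non-missing entries are never
    altered.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not expr["value"].isna().any():
        return expr.copy()
    out = []
    for organ, block in expr.groupby("organ"):
        wide = block.pivot_table(
            index=_SAMPLE_KEYS, columns="gene", values="value", aggfunc="mean", dropna=False
        )
        data = wide.to_numpy(dtype=float)
        if np.isnan(data).any():
            data = _impute_block(data, k, organ)
        filled = pd.DataFrame(data, index=wide.index, columns=wide.columns)
        long = filled.stack().rename("value").reset_index()
        out.append(long)
    res = pd.concat(out, ignore_index=True)
    return res[["animal", "strain", "organ", "age_weeks", "gene", "value"]]


def _impute_block(data: np.ndarray, k: int, organ: str) -> np.ndarray:
    """Impute one organ's sample x gene matrix in place of its NaNs."""
    filled = data.copy()
    n_samples = data.shape[0]
    for s in range(n_samples):
        missing_genes = np.flatnonzero(np.isnan(data[s]))
        if missing_genes.size == 0:
            continue
        # Distance to every other sample over genes observed in both.
        dists = np.full(n_samples, np.inf)
        for other in range(n_samples):
            if other == s:
                continue
            shared = ~np.isnan(data[s]) & ~np.isnan(data[other])
            if not shared.any():
                continue
            diff = data[s, shared] - data[other, shared]
            dists[other] = float(np.sqrt(np.sum(diff**2)))
        for g in missing_genes:
            donors = np.flatnonzero(~np.isnan(data[:, g]) & np.isfinite(dists))
            if donors.size == 0:
                logger.warning("no donor for a missing value in organ %s", organ)
                continue
            if donors.size < k:
                logger.warning(
                    "organ %s: only %d neighbor(s) available (k=%d)",
                    organ,
                    donors.size,
                    k,
                )
            order = donors[np.argsort(dists[donors], kind="stable")][:k]
            filled[s, g] = float(np.mean(data[order, g]))
    return filled


def mean_profiles(expr: pd.DataFrame) -> ProfileSet:
    """Average replicates into per-(strain, organ, gene) mean trajectories.

    Cells absent from the table (e.g. an organ not collected at one age)
    are simply omitted from that profile's time grid, so profiles within
    one strain may carry different numbers of time points.
    """
    ps = ProfileSet()
    grouped = (
        expr.groupby(["strain", "organ", "gene", "age_weeks"])["value"]
        .agg(["mean", "count"])
        .reset_index()
    )
    for (strain, organ, gene), grp in grouped.groupby(["strain", "organ", "gene"]):
        grp = grp.sort_values("age_weeks")
        ps.add(
            Profile(
                strain=strain,
                organ=organ,
                gene=gene,
                times=grp["age_weeks"].to_numpy(dtype=float),
                mean=grp["mean"].to_numpy(dtype=float),
                n_reps=grp["count"].to_numpy(),
            )
        )
    return ps


def scale_profiles(profiles: ProfileSet) -> ProfileSet:
    """Min-max scale every mean profile to [0, 1].

    E_scaled = (E - min E) / (max E - min E).  A constant profile has no
    dynamic range; it maps to all zeros.  The per-profile min/max are
    stored so the transform is invertible.
    """
    out = ProfileSet()
    for p in profiles:
        lo = float(np.min(p.mean))
        hi = float(np.max(p.mean))
        if hi > lo:
            scaled = (p.mean - lo) / (hi - lo)
        else:
            scaled = np.zeros_like(p.mean)
        out.add(
            Profile(
                strain=p.strain,
                organ=p.organ,
                gene=p.gene,
                times=p.times.copy(),
                mean=p.mean.copy(),
                scaled=scaled,
                n_reps=None if p.n_reps is None else np.asarray(p.n_reps).copy(),
                smin=lo,
                smax=hi,
            )
        )
    return out
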