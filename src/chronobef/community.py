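"""Community-level diversity: rarefaction, richness, normalisation,
multidiversity.

Richness is computed from OTU tables rarefied to an even depth per
organism group (300 invertebrates, 800 protists, 2000 fungi, 5000
bacteria by default, configurable per table).  Per-group richness is
0-1 normalised across the whole sample set and the four normalised
scores are averaged into a single multidiversity index per sample.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: canonical organism groups, in reporting order
ORGANISM_GROUPS = ("invertebrates", "protists", "fungi", "bacteria")

#: default rarefaction depth per group
DEFAULT_DEPTHS = {
    "invertebrates": 300,
    "protists": 800,
    "fungi": 2000,
    "bacteria": 5000,
}


@dataclass
class OtuTable:
    """Nonnegative integer counts, OTUs (rows) x samples (columns).

    Parameters
    ----------
    counts
        DataFrame of counts; index = OTU ids (unique), columns = sample ids.
    group
        Organism group name, one of :data:`ORGANISM_GROUPS`.
    rarefaction_depth
        Even sampling depth the table is (to be) rarefied to.
    rarefied
        Whether :func:`rarefy` has been applied.
    """

    counts: pd.DataFrame
    group: str
    rarefaction_depth: int
    rarefied: bool = field(default=False)

    def __post_init__(self) -> None:
        if self.group not in ORGANISM_GROUPS:
            raise ValueError(
                f"unknown organism group {self.group!r}; "
                f"expected one of {ORGANISM_GROUPS}"
            )
        if not self.counts.index.is_unique:
            raise ValueError("OTU ids must be unique")
        vals = self.counts.to_numpy()
        if np.any(vals < 0):
            raise ValueError("OTU counts must be nonnegative")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)


def rarefy(table: OtuTable, depth: int | None = None, seed: int = 0) -> OtuTable:
    """Rarefy every sample column to ``depth`` reads without replacement.

    Each column is subsampled by a multivariate hypergeometric draw so the
    retained columns sum exactly to ``depth``.  Columns whose total is
    below ``depth`` are dropped with a warning.  A column whose total
    equals ``depth`` is returned unchanged.

    The draw for each column is seeded from ``(seed, sample id)``, so the
    result for a sample does not depend on which other samples are present
    or on column order.

    Parameters
    ----------
    table
        Input counts.
    depth
        Target depth; defaults to ``table.rarefaction_depth``.
    seed
        Base seed for the per-column draws.

    Returns
    -------
    OtuTable
        New table with ``rarefied=True``; OTU rows that became all-zero
        are retained (richness counts nonzero entries, so this is
        harmless and keeps row alignment across samples).
    """
    if depth is None:
        depth = table.rarefaction_depth
    if depth <= 0:
        raise ValueError(f"rarefaction depth must be positive, got {depth}")

    counts = table.counts
    totals = counts.sum(axis=0)
    keep = totals >= depth
    dropped = [str(s) for s in totals.index[~keep]]
    if dropped:
        logger.warning(
            "rarefy(%s, depth=%d): dropping %d sample(s) below depth: %s",
            table.group, depth, len(dropped), ", ".join(dropped[:10]),
        )
    if not keep.any():
        raise ValueError(
            f"all {len(totals)} samples of group {table.group!r} are below "
            f"rarefaction depth {depth}"
        )

    out = np.empty((counts.shape[0], int(keep.sum())), dtype=np.int64)
    kept_cols = counts.columns[keep]
    raw = counts.to_numpy(dtype=np.int64)
    col_idx = {c: i for i, c in enumerate(counts.columns)}
    for j, sample in enumerate(kept_cols):
        col = raw[:, col_idx[sample]]
        total = int(col.sum())
        if total == depth:
            out[:, j] = col
            continue
        rng = np.random.default_rng(_column_seed(seed, str(sample)))
        out[:, j] = rng.multivariate_hypergeometric(col, depth)

    rarefied = pd.DataFrame(out, index=counts.index, columns=kept_cols)
    return replace(table, counts=rarefied, rarefied=True)


def _column_seed(seed: int, sample_id: str) -> np.random.SeedSequence:
    # crc32 gives a stable, platform-independent per-sample stream
    return np.random.SeedSequence([int(seed), zlib.crc32(sample_id.encode("utf-8"))])


def richness(table: OtuTable) -> pd.Series:
    """Per-sample richness: number of OTUs with count > 0."""
    r = (table.counts > 0).sum(axis=0)
    r.name = f"richness_{table.group}"
    return r.astype(int)


def minmax_normalize(values: pd.Series | np.ndarray) -> pd.Series | np.ndarray:
    """0-1 normalisation: (x - min) / (max - min), NaNs propagated.

    A constant vector maps every entry to 0.5 (neutral contribution to a
    multi-group mean) with a logged warning.  Requires at least two
    finite values.
    """
    arr = np.asarray(values, dtype=float)
    finite = np.isfinite(arr)
    if finite.sum() < 2:
        raise ValueError("minmax_normalize needs at least 2 finite values")
    lo = arr[finite].min()
    hi = arr[finite].max()
    if hi == lo:
        logger.warning("minmax_normalize: constant input, mapping to 0.5")
        out = np.where(finite, 0.5, np.nan)
    else:
        out = (arr - lo) / (hi - lo)
    if isinstance(values, pd.Series):
        return pd.Series(out, index=values.index, name=values.name)
    return out


def multidiversity(normalized: dict[str, pd.Series]) -> pd.Series:
    """Arithmetic mean of the four groups' 0-1 normalised richness.

    Parameters
    ----------
    normalized
        Mapping group name -> normalised richness per sample; must contain
        every group in :data:`ORGANISM_GROUPS`, aligned on sample id.
    """
    missing = [g for g in ORGANISM_GROUPS if g not in normalized]
    if missing:
        raise ValueError(f"multidiversity: missing group(s) {missing}")
    frame = pd.DataFrame({g: normalized[g] for g in ORGANISM_GROUPS})
    vals = frame.to_numpy(dtype=float)
    if np.nanmin(vals) < -1e-12 or np.nanmax(vals) > 1 + 1e-12:
        raise ValueError("normalised richness must lie in [0, 1]")
    md = frame.mean(axis=1)
    md.name = "multidiversity"
    return md


def diversity_profile(
    otu_tables: dict[str, OtuTable],
    seed: int = 0,
    normalization_scope: str = "global",
    groups_for_scope: pd.Series | None = None,
) -> pd.DataFrame:
    """Full diversity table: rarefy each group, compute richness, normalise,
    and average into multidiversity.

    Parameters
    ----------
    otu_tables
        One raw (or already rarefied) table per organism group.
    seed
        Seed forwarded to :func:`rarefy`.
    normalization_scope
        ``"global"`` (default): richness is normalised across all samples,
        so multidiversity is comparable between plots and chronosequences.
        ``"per_group_label"``: normalise within the grouping given by
        ``groups_for_scope`` (e.g. per chronosequence).
    groups_for_scope
        Sample id -> scope label, required for non-global scope.

    Returns
    -------
    DataFrame indexed by sample id with ``richness_<group>``,
    ``norm_<group>`` and ``multidiversity`` columns.  Samples dropped
    during rarefaction of any group are excluded.
    """
    rich: dict[str, pd.Series] = {}
    for group in ORGANISM_GROUPS:
        if group not in otu_tables:
            raise ValueError(f"diversity_profile: missing OTU table for {group!r}")
        table = otu_tables[group]
        if not table.rarefied:
            table = rarefy(table, seed=seed)
        rich[group] = richness(table)

    common = rich[ORGANISM_GROUPS[0]].index
    for group in ORGANISM_GROUPS[1:]:
        common = common.intersection(rich[group].index)
    out = pd.DataFrame(index=common)
    out.index.name = "sample_id"
    norm: dict[str, pd.Series] = {}
    for group in ORGANISM_GROUPS:
        r = rich[group].loc[common]
        out[f"richness_{group}"] = r
        if normalization_scope == "global":
            n = minmax_normalize(r.astype(float))
        elif normalization_scope == "per_group_label":
            if groups_for_scope is None:
                raise ValueError("groups_for_scope required for per-label scope")
            labels = groups_for_scope.loc[common]
            n = r.astype(float).groupby(labels).transform(
                lambda v: pd.Series(minmax_normalize(v), index=v.index)
            )
        else:
            raise ValueError(f"unknown normalization scope {normalization_scope!r}")
        out[f"norm_{group}"] = n
        norm[group] = n
    out["multidiversity"] = multidiversity(norm)
    return out
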