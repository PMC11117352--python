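"""Aggregation of pipeline outputs into the survey's three table shapes,
plus family-by-family protein similarity matrices.

The same aggregations run on pipeline outputs and on the bundled
literature-derived reference tabulations (``tetraltr.data``), which lets the
table invariants (monotone mining funnel, rollup sums, symmetry) be checked
against published summary values without network access.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .classify import pairwise_identity
from .families import FAMILY_TO_SUPERFAMILY
from .seq_core import ProteinSequence

logger = logging.getLogger(__name__)

FUNNEL_COLUMNS = ["identified", "length_filtered", "full_length"]


def _fixture(name: str) -> pd.DataFrame:
    ref = resources.files("tetraltr.data") / name
    with resources.as_file(ref) as p:
        return pd.read_csv(p, sep="\t")


def load_funnel_fixture() -> pd.DataFrame:
    return _fixture("tetraodontiformes_funnel.tsv")


def load_elements_fixture() -> pd.DataFrame:
    return _fixture("tetraodontiformes_elements.tsv")


def load_distribution_fixture() -> pd.DataFrame:
    df = _fixture("tetraodontiformes_distribution.tsv")
    return df.set_index("family")


# --- funnel ----------------------------------------------------------------


def summarize_funnel(counts: pd.DataFrame | dict) -> pd.DataFrame:
    """Per-genome mining funnel with a totals row.

    ``counts``: mapping genome -> (identified, length_filtered, full_length)
    or a DataFrame with those columns indexed/keyed by genome.  Raises when
    any row is non-monotone (identified >= length_filtered >= full_length).
    """
    if isinstance(counts, dict):
        df = pd.DataFrame.from_dict(counts, orient="index", columns=FUNNEL_COLUMNS)
        df.index.name = "genome"
    else:
        df = counts.copy()
        if "species" in df.columns:
            df = df.set_index("species")
        df = df[FUNNEL_COLUMNS]
    bad = df[
        (df.identified < df.length_filtered) | (df.length_filtered < df.full_length)
    ]
    if len(bad):
        raise ValueError(f"non-monotone funnel rows: {list(bad.index)}")
    totals = df.sum()
    out = pd.concat([df, totals.to_frame("Total").T])
    out.index.name = df.index.name
    return out.astype(int)


# --- element table ---------------------------------------------------------


@dataclass
class ElementSummary:
    elements: pd.DataFrame  # one row per element
    family_rollup: pd.DataFrame  # copies / full LTR counts per family
    superfamily_rollup: pd.DataFrame
    n_elements: int
    consensus_range: tuple[int, int]
    ltr_range: tuple[int, int]
    max_copy_count: int


def summarize_elements(elements: pd.DataFrame) -> ElementSummary:
    """Family and superfamily rollups from a per-element table.

    Expects columns family, element, copies, full_ltr (others are carried
    through).  Family copy counts are sums over their elements.
    """
    df = elements.copy()
    df["superfamily"] = df["family"].map(FAMILY_TO_SUPERFAMILY)
    if df["superfamily"].isna().any():
        missing = df.loc[df["superfamily"].isna(), "family"].unique()
        raise ValueError(f"unknown families: {list(missing)}")
    agg = {"copies": "sum", "full_ltr": "sum", "element": "count"}
    fam = df.groupby("family").agg(agg).rename(columns={"element": "n_elements"})
    sf = df.groupby("superfamily").agg(agg).rename(columns={"element": "n_elements"})
    return ElementSummary(
        elements=df,
        family_rollup=fam,
        superfamily_rollup=sf,
        n_elements=len(df),
        consensus_range=(int(df.consensus_bp.min()), int(df.consensus_bp.max())),
        ltr_range=(int(df.ltr_bp.min()), int(df.ltr_bp.max())),
        max_copy_count=int(df.copies.max()),
    )


# --- distribution matrix ---------------------------------------------------


@dataclass
class DistributionSummary:
    families: pd.DataFrame  # family x species counts
    superfamilies: pd.DataFrame  # superfamily x species counts
    totals: pd.Series  # per-species totals (sum of superfamily rows)
    species_presence: pd.Series  # per-superfamily count of species with >0


def summarize_distribution(families: pd.DataFrame) -> DistributionSummary:
    """Superfamily rollups, per-species totals and presence counts from a
    family x species count matrix (families as index)."""
    if (families.values < 0).any():
        raise ValueError("distribution counts must be >= 0")
    unknown = [f for f in families.index if f not in FAMILY_TO_SUPERFAMILY]
    if unknown:
        raise ValueError(f"unknown families: {unknown}")
    sf = families.groupby(families.index.map(FAMILY_TO_SUPERFAMILY)).sum()
    sf.index.name = "superfamily"
    totals = sf.sum()
    presence = (sf > 0).sum(axis=1)
    return DistributionSummary(families, sf, totals, presence)


# --- similarity matrices ---------------------------------------------------


def similarity_heatmap(
    proteins_by_family: dict[str, list[ProteinSequence]],
    method: str = "affine",
) -> tuple[pd.DataFrame, pd.Series]:
    """Mean pairwise identity (%) within and between families.

    Diagonal cells average all within-family pairs (NaN for singleton
    families, which are flagged in the log); off-diagonal cells average all
    cross-family pairs.  Returns (symmetric matrix, per-family n).
    """
    fams = sorted(proteins_by_family)
    n = pd.Series({f: len(proteins_by_family[f]) for f in fams})
    mat = pd.DataFrame(np.nan, index=fams, columns=fams, dtype=float)
    for i, fa in enumerate(fams):
        pa = proteins_by_family[fa]
        for fb in fams[i:]:
            pb = proteins_by_family[fb]
            if fa == fb:
                pairs = [
                    pairwise_identity(pa[x], pa[y], method=method)
                    for x in range(len(pa))
                    for y in range(x + 1, len(pa))
                ]
                if not pairs:
                    logger.info("similarity_heatmap: singleton family %s", fa)
            else:
                pairs = [
                    pairwise_identity(x, y, method=method) for x in pa for y in pb
                ]
            if pairs:
                val = float(np.mean(pairs))
                mat.loc[fa, fb] = val
                mat.loc[fb, fa] = val
    return mat, n
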