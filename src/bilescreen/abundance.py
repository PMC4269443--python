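"""Depth-normalised gene-family abundance: hits per million reads searched.

One read counts once per gene family no matter how many database proteins
it matched (read-level counting, so database redundancy cannot inflate
abundance).  Counts are stratified per family as:

* ``TOTAL`` — all hit reads,
* ``ASSIGNED`` — hit reads with a taxonomic assignment,
* ``phylum:X`` / ``taxfamily:Y`` — assigned reads at that rank, with reads
  whose tie-resolved lineage is blank at the rank collected under
  ``...:unassigned_at_level``,
* ``cluster:K`` — Firmicute species-level reads mapped through a BSH
  protein-cluster map, the remainder under ``cluster:unclustered``.

Strata at a rank (plus its unassigned-at-level bucket) always sum exactly
to ASSIGNED; cluster strata plus unclustered sum to the Firmicute
species-level total.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

ABUNDANCE_COLUMNS = ["sample_id", "group", "family", "stratum", "hits", "hits_per_million"]

UNASSIGNED_AT_LEVEL = "unassigned_at_level"
UNCLUSTERED = "unclustered"
LEVELS = ("TOTAL", "ASSIGNED", "phylum", "taxfamily", "cluster")


def hits_per_million(hit_count: int, total_reads: int) -> float:
    """hit_count / total_reads × 10⁶."""
    if total_reads < 1:
        raise ValueError("total_reads must be >= 1")
    if hit_count < 0:
        raise ValueError("hit_count must be >= 0")
    return hit_count / total_reads * 1e6


def sample_strata(
    hits: pd.DataFrame,
    assignments: pd.DataFrame,
    total_reads: int,
    cluster_of: Mapping[str, int] | None = None,
    cluster_phylum: str = "Firmicutes",
) -> pd.DataFrame:
    """Stratified hit counts for one sample; rows (family, stratum, hits)."""
    rows: list[tuple[str, str, int]] = []
    if len(hits) == 0:
        return pd.DataFrame(columns=["family", "stratum", "hits"])
    asg = assignments.set_index("read_index") if len(assignments) else pd.DataFrame()
    for family, grp in hits.groupby("family", sort=True):
        reads = np.unique(grp["read_index"].to_numpy(dtype=np.int64))
        rows.append((family, "TOTAL", len(reads)))
        if len(asg) == 0:
            rows.append((family, "ASSIGNED", 0))
            continue
        sub = asg.reindex(reads)
        assigned = sub[sub["genome_id"].fillna("") != ""]
        rows.append((family, "ASSIGNED", len(assigned)))
        for level, col in (("phylum", "phylum"), ("taxfamily", "tax_family")):
            vals = assigned[col].fillna("")
            for name, cnt in vals.value_counts().items():
                stratum = f"{level}:{name}" if name else f"{level}:{UNASSIGNED_AT_LEVEL}"
                rows.append((family, stratum, int(cnt)))
        if cluster_of is not None:
            firm = assigned[
                (assigned["phylum"] == cluster_phylum) & (assigned["species"] != "")
            ]
            ks = firm["species"].map(lambda s: cluster_of.get(s))
            for k, cnt in ks.value_counts(dropna=False).items():
                stratum = f"cluster:{UNCLUSTERED}" if pd.isna(k) else f"cluster:{int(k)}"
                rows.append((family, stratum, int(cnt)))
    df = pd.DataFrame(rows, columns=["family", "stratum", "hits"])
    return df.groupby(["family", "stratum"], as_index=False, sort=True)["hits"].sum()


def cohort_abundance(
    per_sample: list[tuple[str, str, pd.DataFrame, pd.DataFrame, int]],
    cluster_of: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Long-format abundance table over (sample_id, group, hits, assignments,
    total_reads) tuples, densified so every sample carries every stratum."""
    frames = []
    for sample_id, group, hits, assignments, total_reads in per_sample:
        strata = sample_strata(hits, assignments, total_reads, cluster_of)
        strata.insert(0, "sample_id", sample_id)
        strata.insert(1, "group", group)
        strata["hits_per_million"] = [
            hits_per_million(int(h), total_reads) for h in strata["hits"]
        ]
        frames.append(strata)
    long = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=ABUNDANCE_COLUMNS)
    if len(long) == 0:
        return long
    # densify: missing (sample, family, stratum) combinations are zeros
    full = (
        long.set_index(["sample_id", "group", "family", "stratum"])
        .unstack(["family", "stratum"], fill_value=0)
        .stack(["family", "stratum"], future_stack=True)
        .reset_index()
    )
    return full[ABUNDANCE_COLUMNS].sort_values(
        ["sample_id", "family", "stratum"], ignore_index=True
    )


def to_wide(
    long_df: pd.DataFrame, family: str, level: str, value: str = "hits_per_million"
) -> pd.DataFrame:
    """Samples × strata matrix for one family at one level.

    ``level`` is TOTAL, ASSIGNED, phylum, taxfamily or cluster.
    """
    if level not in LEVELS:
        raise ValueError(f"unknown level {level!r}; expected one of {LEVELS}")
    sub = long_df[long_df["family"] == family]
    if level in ("TOTAL", "ASSIGNED"):
        sub = sub[sub["stratum"] == level]
    else:
        sub = sub[sub["stratum"].str.startswith(f"{level}:")]
    wide = sub.pivot_table(
        index=["sample_id", "group"], columns="stratum", values=value,
        aggfunc="first", fill_value=0.0,
    )
    wide.columns.name = None
    return wide.reset_index().set_index("sample_id")
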