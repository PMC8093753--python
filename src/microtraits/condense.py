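"""Condense multi-record trait tables to one row per species.

Trait databases carry anywhere from one to thousands of records per species
(genotypes, 16S phylotypes, repeated culture measurements). For comparative
analysis these are condensed to species level: quantitative traits are
averaged on their natural scale after robust outlier removal, categorical
traits take a strict-majority value, and taxa whose biology breaks the
assumptions of the analysis (obligate intracellular species, the mycoplasma
group) can be excluded.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

RANKS = ("superkingdom", "phylum", "class", "order", "family", "genus", "species")

#: quantitative trait columns, averaged per species
QUANT_TRAITS = (
    "cell_diameter_um",
    "genome_size_bp",
    "mu_max_per_h",
    "growth_temp_C",
    "rrn_copies",
)
#: strictly-positive quantitative traits, outlier-screened on log10 scale
POSITIVE_TRAITS = ("cell_diameter_um", "genome_size_bp", "mu_max_per_h", "rrn_copies")
#: categorical traits, condensed by strict majority (ties -> missing)
CAT_TRAITS = ("habitat", "shape", "trophic")
#: boolean flags, condensed as any-record-True
BOOL_TRAITS = ("intracellular", "mycoplasma")

MODIFIED_Z_THRESHOLD = 3.5
MIN_OUTLIER_N = 4


def resolve_diameter(value, record_id=None):
    """Resolve a reported cell diameter to a single positive scalar (um).

    Diameters are reported either as a single number or as a (min, max)
    range; a range resolves to its arithmetic midpoint. For rods the value
    is the radial (width) dimension, not the cell length.
    """
    ctx = f" (record {record_id})" if record_id is not None else ""
    if isinstance(value, (tuple, list)):
        if len(value) != 2:
            raise ValueError(f"diameter range must have two endpoints{ctx}: {value!r}")
        lo, hi = float(value[0]), float(value[1])
        if not (0 < lo <= hi):
            raise ValueError(
                f"diameter range must satisfy 0 < min <= max{ctx}: ({lo}, {hi})"
            )
        return 0.5 * (lo + hi)
    d = float(value)
    if not np.isfinite(d) or d <= 0:
        raise ValueError(f"diameter must be positive{ctx}: {value!r}")
    return d


def flag_outliers(values):
    """Flag gross outliers among positive trait values.

    Uses the modified z-score |0.6745*(x - median)/MAD| > 3.5 on log10
    values. Applied only when there are at least four values and the MAD is
    positive; degenerate inputs return an all-False mask. Returns a boolean
    mask marking values to exclude from averaging.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("flag_outliers expects a non-empty 1-D sequence")
    if not np.all(np.isfinite(x)) or np.any(x <= 0):
        raise ValueError("flag_outliers expects finite positive values")
    mask = np.zeros(x.size, dtype=bool)
    if x.size < MIN_OUTLIER_N:
        return mask
    lx = np.log10(x)
    med = np.median(lx)
    mad = np.median(np.abs(lx - med))
    if mad == 0:
        return mask
    return np.abs(0.6745 * (lx - med) / mad) > MODIFIED_Z_THRESHOLD


def _majority(series: pd.Series):
    vals = series.dropna()
    if len(vals) == 0:
        return np.nan
    counts = vals.value_counts()
    top = counts.iloc[0]
    if top * 2 > len(vals) and (len(counts) == 1 or counts.iloc[1] < top):
        return counts.index[0]
    return np.nan  # tie or no strict majority: do not fabricate a value


def _robust_mean(series: pd.Series, screen: bool) -> float:
    vals = series.dropna().to_numpy(dtype=float)
    if vals.size == 0:
        return np.nan
    if screen:
        vals = vals[~flag_outliers(vals)]
    return float(vals.mean())


def condense_records(records: pd.DataFrame) -> pd.DataFrame:
    """Condense a record-level trait table to one row per species.

    Quantitative traits become the arithmetic mean (natural scale) of
    non-missing, non-outlier values; categorical traits a strict-majority
    value (ties -> missing); booleans True if any record is True.
    ``n_records`` counts contributing records. Conflicting taxonomy above
    the species rank for a single species name is an error.

    Accepts an already-condensed table (idempotent: re-condensing preserves
    values and sums existing ``n_records``).
    """
    if records is None or len(records) == 0:
        raise ValueError("cannot condense an empty record table")
    df = records.copy()
    if "species" not in df.columns:
        raise ValueError("record table lacks a 'species' column")
    if df["species"].isna().any() or (df["species"].astype(str).str.len() == 0).any():
        raise ValueError("every record must carry a non-empty species name")

    # taxonomy consistency above species rank
    upper = [r for r in RANKS[:-1] if r in df.columns]
    if upper:
        nuniq = df.groupby("species")[upper].nunique(dropna=False)
        bad = nuniq[(nuniq > 1).any(axis=1)].index.tolist()
        if bad:
            raise ValueError(
                f"conflicting taxonomy above species rank for: {', '.join(map(str, bad[:5]))}"
            )

    if "cell_diameter_um" in df.columns:
        col = df["cell_diameter_um"]
        rid = df["record_id"] if "record_id" in df.columns else df.index
        df["cell_diameter_um"] = [
            np.nan if _is_missing(v) else resolve_diameter(v, record_id=r)
            for v, r in zip(col, rid)
        ]

    rows = []
    for species, grp in df.groupby("species", sort=True):
        row = {"species": species}
        for r in upper:
            row[r] = grp[r].iloc[0]
        for trait in QUANT_TRAITS:
            if trait in grp.columns:
                row[trait] = _robust_mean(grp[trait], screen=trait in POSITIVE_TRAITS)
        for trait in CAT_TRAITS:
            if trait in grp.columns:
                row[trait] = _majority(grp[trait])
        for trait in BOOL_TRAITS:
            if trait in grp.columns:
                row[trait] = bool(grp[trait].fillna(False).astype(bool).any())
        if "n_records" in grp.columns:
            row["n_records"] = int(grp["n_records"].sum())
        else:
            row["n_records"] = int(len(grp))
        rows.append(row)

    out = pd.DataFrame(rows)
    if "rrn_copies" in out.columns:
        rrn = out["rrn_copies"]
        out["rrn_copies"] = np.where(rrn.notna(), np.maximum(np.round(rrn), 1.0), np.nan)
    cols = (
        ["species"]
        + upper
        + [c for c in QUANT_TRAITS + CAT_TRAITS + BOOL_TRAITS if c in out.columns]
        + ["n_records"]
    )
    return out[cols]


def _is_missing(v) -> bool:
    if isinstance(v, (tuple, list)):
        return False
    try:
        return bool(pd.isna(v))
    except (TypeError, ValueError):
        return False


def filter_taxa(table: pd.DataFrame, include_intracellular: bool = False) -> pd.DataFrame:
    """Drop intracellular species and the mycoplasma group unless included.

    Species living inside eukaryote cells, and mycoplasmas as a group, have
    strongly reduced genomes for reasons unrelated to oligotrophy, so the
    main analysis excludes them. With ``include_intracellular=True`` the
    table is returned unchanged. The number of removed rows is logged.
    """
    if include_intracellular:
        return table
    drop = pd.Series(False, index=table.index)
    if "intracellular" in table.columns:
        drop |= table["intracellular"].fillna(False).astype(bool)
    if "mycoplasma" in table.columns:
        drop |= table["mycoplasma"].fillna(False).astype(bool)
    if "genus" in table.columns:
        drop |= (
            table["genus"].astype(str).str.lower().str.contains("mycoplasma", na=False)
        )
    n_removed = int(drop.sum())
    logger.info("filter_taxa: removed %d intracellular/mycoplasma species", n_removed)
    return table.loc[~drop].reset_index(drop=True)
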