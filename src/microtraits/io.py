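"""CSV input/output for record and species trait tables.

The canonical tabular format is RFC-4180 CSV. Taxonomy is accepted either
as seven separate rank columns (superkingdom..species) or as a single
semicolon-delimited string column named ``taxonomy`` in the
``d__...;p__...;...;s__...`` style; rank prefixes (``d__``, ``p__``, ...)
are stripped on read in both dialects, and the seven rank columns are
written back on output. Numeric output files carry the
seed and a config hash in a ``#`` comment header.
"""

from __future__ import annotations

import hashlib
import json
import logging
import re

import numpy as np
import pandas as pd

from . import __version__
from .condense import BOOL_TRAITS, QUANT_TRAITS, RANKS

logger = logging.getLogger(__name__)

_RANGE_RE = re.compile(r"^\s*([0-9.eE+]+)\s*[-–]\s*([0-9.eE+]+)\s*$")
_PREFIX_RE = re.compile(r"^[a-z]__")
_TRUTHY = {"true", "1", "yes", "t", "y"}


def _parse_diameter_cell(v):
    """A diameter cell is a number, a 'min-max' range string, or missing."""
    if v is None or (isinstance(v, float) and np.isnan(v)):
        return np.nan
    if isinstance(v, (int, float)):
        return float(v)
    s = str(v).strip()
    if s == "" or s.lower() == "nan":
        return np.nan
    m = _RANGE_RE.match(s)
    if m:
        return (float(m.group(1)), float(m.group(2)))
    return float(s)


def _parse_bool_cell(v):
    if isinstance(v, (bool, np.bool_)):
        return bool(v)
    if v is None or (isinstance(v, float) and np.isnan(v)):
        return False
    return str(v).strip().lower() in _TRUTHY


def read_trait_table(path, strict: bool = True) -> pd.DataFrame:
    """Read and validate a record-level trait CSV.

    Malformed rows (non-positive trait values, inverted diameter ranges,
    empty species names) are reported with their file line numbers; in
    strict mode any malformed row is fatal, in lenient mode the rows are
    skipped and logged. Duplicate record ids and missing taxonomy columns
    are always fatal.
    """
    df = pd.read_csv(path, comment="#", dtype={"taxonomy": str})
    if "taxonomy" in df.columns:
        parts = df["taxonomy"].astype(str).str.split(";")
        bad = parts.str.len() != len(RANKS)
        if bad.any():
            lines = (df.index[bad] + 2).tolist()
            raise ValueError(
                f"{path}: taxonomy strings without {len(RANKS)} ranks at lines {lines[:10]}"
            )
        for i, rank in enumerate(RANKS):
            df[rank] = parts.str[i].str.strip().map(lambda s: _PREFIX_RE.sub("", s))
        df = df.drop(columns=["taxonomy"])
    elif all(r in df.columns for r in RANKS):
        for rank in RANKS:
            df[rank] = (
                df[rank].astype(str).str.strip().map(lambda s: _PREFIX_RE.sub("", s))
            )
            df.loc[df[rank].isin(["nan", ""]), rank] = np.nan
    else:
        missing = [r for r in RANKS if r not in df.columns]
        raise ValueError(
            f"{path}: need either a 'taxonomy' column or all rank columns (missing {missing})"
        )

    if "record_id" in df.columns:
        dup = df["record_id"][df["record_id"].duplicated()]
        if len(dup):
            raise ValueError(f"{path}: duplicate record ids: {dup.unique()[:5].tolist()}")
    else:
        df.insert(0, "record_id", [f"row{i + 2}" for i in df.index])

    for trait in QUANT_TRAITS:
        if trait in df.columns and trait != "cell_diameter_um":
            df[trait] = pd.to_numeric(df[trait], errors="coerce")
    for trait in BOOL_TRAITS:
        if trait in df.columns:
            df[trait] = df[trait].map(_parse_bool_cell)
        else:
            df[trait] = False

    problems = []  # (line_number, message)
    if "cell_diameter_um" in df.columns:
        parsed = []
        for idx, v in df["cell_diameter_um"].items():
            try:
                parsed.append(_parse_diameter_cell(v))
            except ValueError:
                problems.append((idx + 2, f"unparseable diameter {v!r}"))
                parsed.append(np.nan)
        df["cell_diameter_um"] = pd.Series(parsed, index=df.index, dtype=object)
        for idx, v in df["cell_diameter_um"].items():
            if isinstance(v, tuple):
                if not (0 < v[0] <= v[1]):
                    problems.append((idx + 2, f"invalid diameter range {v}"))
            elif isinstance(v, float) and np.isfinite(v) and v <= 0:
                problems.append((idx + 2, f"non-positive diameter {v}"))
    for trait in ("genome_size_bp", "mu_max_per_h", "rrn_copies"):
        if trait in df.columns:
            bad = df[trait].notna() & (df[trait] <= 0)
            problems.extend((i + 2, f"non-positive {trait}") for i in df.index[bad])
    empty_sp = df["species"].isna() | (df["species"].astype(str).str.strip() == "")
    problems.extend((i + 2, "empty species name") for i in df.index[empty_sp])

    if problems:
        problems.sort()
        msg = "; ".join(f"line {ln}: {m}" for ln, m in problems[:10])
        if strict:
            raise ValueError(f"{path}: {len(problems)} malformed rows ({msg})")
        bad_rows = {ln - 2 for ln, _ in problems}
        logger.warning("%s: skipping %d malformed rows (%s)", path, len(bad_rows), msg)
        df = df.drop(index=sorted(bad_rows)).reset_index(drop=True)
    return df


def _format_diameter(v):
    if isinstance(v, tuple):
        return f"{v[0]}-{v[1]}"
    return v


def config_hash(obj) -> str:
    """Stable short hash of any JSON-serializable configuration object."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha1(payload).hexdigest()[:12]


def write_table(df: pd.DataFrame, path, seed=None, cfg_hash=None) -> None:
    """Write a table as CSV with a provenance comment header."""
    out = df.copy()
    if "cell_diameter_um" in out.columns and out["cell_diameter_um"].dtype == object:
        out["cell_diameter_um"] = out["cell_diameter_um"].map(_format_diameter)
    with open(path, "w", newline="") as fh:
        fh.write(f"# microtraits v{__version__}; seed={seed}; config={cfg_hash}\n")
        out.to_csv(fh, index=False)


def read_species_table(path) -> pd.DataFrame:
    """Read a condensed species-level CSV (as written by ``write_table``)."""
    df = pd.read_csv(path, comment="#")
    for trait in BOOL_TRAITS:
        if trait in df.columns:
            df[trait] = df[trait].map(_parse_bool_cell)
    return df


def write_correlation_outputs(corr, prefix, seed=None, cfg_hash=None) -> None:
    """Write a correlation matrix as two CSVs: r^2 values and pair counts."""
    write_table(corr.r2.reset_index(names="trait"), f"{prefix}_r2.csv", seed, cfg_hash)
    write_table(corr.n.reset_index(names="trait"), f"{prefix}_n.csv", seed, cfg_hash)
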