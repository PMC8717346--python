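"""Reading, validation and derivation of the element / song / life-history tables.

The atomic input is the *element table*: one row per song element (a single
continuous spectrogram trace) with identifier columns and ~23 named acoustic
measurements. Song-level parameters (duration, element number/rate, frequency
extremes) are derived from it; the element-diversity column is filled later by
the geometry stage. Life-history covariates live in a per-population table.

All tables are plain :class:`pandas.DataFrame` objects validated on entry;
delimited text on disk (TSV default, comma autodetected), plus a Raven
selection-table dialect for element measurements, and Newick for trees.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "ID_COLUMNS",
    "ELEMENT_FEATURES",
    "SONG_PARAMETERS",
    "LIFE_HISTORY_COVARIATES",
    "FormatError",
    "ValidationError",
    "read_element_table",
    "write_element_table",
    "derive_song_table",
    "prune_correlated_features",
    "check_collinearity",
    "read_newick",
    "read_life_history_table",
    "read_table",
]

#: Identifier columns every element row must carry.
ID_COLUMNS = ("song_id", "individual_id", "population", "species", "sex")

#: Canonical element-level acoustic parameters. Robust time/frequency
#: measurements (duration percentiles, frequency percentiles, bandwidths,
#: peak-frequency contour statistics) plus spectral-shape parameters
#: (entropies, flatness, modulation index, frequency moments). ``freq_95``
#: is carried alongside the analysis set because the song-level frequency
#: extremes aggregate it.
ELEMENT_FEATURES = (
    "duration_90",
    "iqr_duration",
    "center_time",
    "freq_5",
    "freq_25",
    "freq_75",
    "freq_95",
    "bandwidth_90",
    "iqr_bandwidth",
    "peak_freq",
    "max_peak_freq_contour",
    "range_peak_freq_contour",
    "peak_freq_slope",
    "inflections_peak_freq_contour",
    "mean_freq",
    "sd_freq",
    "median_freq",
    "skewness",
    "time_entropy",
    "entropy",
    "flatness",
    "modulation_index",
    "dom_freq_slope",
)

#: Columns that may arrive blank and are filled with zero: elements too short
#: to support a frequency-slope estimate show no meaningful modulation.
ZERO_IMPUTED_FEATURES = ("dom_freq_slope",)

#: The seven song-level acoustic parameters.
SONG_PARAMETERS = (
    "song_duration",
    "element_number",
    "element_rate",
    "freq_5",
    "freq_95",
    "freq_range",
    "element_diversity",
)

#: Population-level life-history covariates used as model predictors.
LIFE_HISTORY_COVARIATES = (
    "epp",
    "brood_size",
    "breeding_synchrony",
    "group_size",
    "breeding_male_density",
    "male_provisioning",
    "male_survival",
    "latitude",
)

_RAVEN_COLUMN_MAP = {
    "Begin Time (s)": "start_time",
    "End Time (s)": "end_time",
}


class FormatError(ValueError):
    """A file does not conform to the expected dialect/column layout."""


class ValidationError(ValueError):
    """A parsed table violates a structural invariant."""


def _read_delimited(path: str | Path) -> pd.DataFrame:
    """Read delimited text; tab by default, comma autodetected from the header."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if "\t" in header else ("," if "," in header else r"\s+")
    return pd.read_csv(path, sep=sep)


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a generic delimited table (TSV default, comma autodetected)."""
    return _read_delimited(path)


def read_element_table(
    path: str | Path,
    dialect: str = "plain",
    features: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Read and validate an element-level measurement table.

    Parameters
    ----------
    path
        Delimited text file. ``plain``: a header names the identifier and
        feature columns directly. ``raven_selection``: a tab-separated Raven
        selection table whose "Begin Time (s)" / "End Time (s)" columns map
        to ``start_time`` / ``end_time``.
    dialect
        ``"plain"`` or ``"raven_selection"``.
    features
        Feature columns to require; defaults to whichever canonical
        :data:`ELEMENT_FEATURES` appear in the file (at least one required).

    Returns
    -------
    DataFrame sorted by ``(song_id, start_time)`` with identifier, time and
    feature columns. Blank cells in :data:`ZERO_IMPUTED_FEATURES` become 0.0;
    any other missing feature cell raises.
    """
    if dialect not in ("plain", "raven_selection"):
        raise ValueError(f"unknown dialect: {dialect!r}")
    if dialect == "raven_selection":
        df = pd.read_csv(path, sep="\t")
        df = df.rename(columns=_RAVEN_COLUMN_MAP)
        df = df.drop(columns=[c for c in ("Selection", "View", "Channel") if c in df])
    else:
        df = _read_delimited(path)

    for col in (*ID_COLUMNS, "start_time", "end_time"):
        if col not in df.columns:
            raise FormatError(f"missing mandatory column: {col!r}")

    if features is None:
        features = tuple(f for f in ELEMENT_FEATURES if f in df.columns)
    missing = [f for f in features if f not in df.columns]
    if missing:
        raise FormatError(f"missing feature column(s): {missing}")
    if not features:
        raise FormatError("no recognized acoustic feature columns present")

    return validate_element_table(df, features=features)


def validate_element_table(
    df: pd.DataFrame, features: tuple[str, ...] | None = None
) -> pd.DataFrame:
    """Enforce the element-table invariants; returns a normalized copy."""
    df = df.copy()
    if features is None:
        features = tuple(f for f in ELEMENT_FEATURES if f in df.columns)

    sex = df["sex"].astype(str).str.strip().str.lower()
    sex = sex.replace({"m": "male", "f": "female"})
    bad = ~sex.isin(["male", "female"])
    if bad.any():
        raise ValidationError(
            f"sex values outside male/female: {sorted(df['sex'][bad].unique())}"
        )
    df["sex"] = sex
    for col in ("song_id", "individual_id", "population", "species"):
        df[col] = df[col].astype(str).str.strip()

    bad_rows = df.index[df["end_time"].to_numpy() <= df["start_time"].to_numpy()]
    if len(bad_rows):
        raise ValidationError(
            f"elements with end_time <= start_time at rows {list(bad_rows[:10])}"
        )

    for col in features:
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            if col in ZERO_IMPUTED_FEATURES:
                vals = vals.fillna(0.0)
            else:
                raise ValidationError(
                    f"missing/non-numeric values in feature {col!r} "
                    f"(only {ZERO_IMPUTED_FEATURES} may be blank)"
                )
        df[col] = vals.astype(float)
        if not np.isfinite(df[col]).all():
            raise ValidationError(f"non-finite values in feature {col!r}")

    # one (individual, population, species, sex) per song
    meta = df.groupby("song_id")[["individual_id", "population", "species", "sex"]].nunique()
    inconsistent = meta.index[(meta > 1).any(axis=1)]
    if len(inconsistent):
        raise ValidationError(
            f"songs with inconsistent identifiers: {list(inconsistent[:5])}"
        )

    df = df.sort_values(["song_id", "start_time"], kind="stable").reset_index(drop=True)
    df.attrs["features"] = tuple(features)
    return df


def write_element_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write an element table as TSV (round-trips with the plain dialect)."""
    df.to_csv(path, sep="\t", index=False)


def derive_song_table(elements: pd.DataFrame) -> pd.DataFrame:
    """Aggregate element rows into the seven song-level acoustic parameters.

    Per song: ``song_duration`` = span of element times; ``element_number`` =
    element count; ``element_rate`` = number / duration; ``freq_5`` (``freq_95``)
    = min (max) over elements of the element-level 5% (95%) frequency;
    ``freq_range`` = their difference; ``element_diversity`` left NaN until the
    geometry stage fills it.
    """
    for col in ("freq_5", "freq_95"):
        if col not in elements.columns:
            raise ValidationError(f"element table lacks {col!r}, required for song table")
    g = elements.groupby("song_id", sort=True)
    out = g.agg(
        individual_id=("individual_id", "first"),
        population=("population", "first"),
        species=("species", "first"),
        sex=("sex", "first"),
        _t0=("start_time", "min"),
        _t1=("end_time", "max"),
        element_number=("start_time", "size"),
        freq_5=("freq_5", "min"),
        freq_95=("freq_95", "max"),
    ).reset_index()
    out["song_duration"] = out["_t1"] - out["_t0"]
    if (out["song_duration"] <= 0).any():
        bad = out.loc[out["song_duration"] <= 0, "song_id"].tolist()
        raise ValidationError(f"songs with non-positive duration: {bad[:5]}")
    out["element_rate"] = out["element_number"] / out["song_duration"]
    out["freq_range"] = out["freq_95"] - out["freq_5"]
    out["element_diversity"] = np.nan
    cols = ["song_id", "individual_id", "population", "species", "sex", *SONG_PARAMETERS]
    return out[cols]


def prune_correlated_features(
    X: pd.DataFrame, threshold: float = 0.95
) -> tuple[pd.DataFrame, list[str], list[str]]:
    """Greedily drop the later column of any pair with Pearson ``|r| >= threshold``.

    Zero-variance columns are dropped first (their correlation is undefined).
    The scan visits column pairs in input order, so the result is deterministic
    for a fixed column order, and the operation is idempotent.

    Returns ``(reduced, dropped, kept)``.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    if X.shape[1] < 2 or X.shape[0] < 3:
        raise ValueError("need >=2 columns and >=3 rows")
    cols = list(X.columns)
    dropped: list[str] = []
    values = X.to_numpy(dtype=float)
    variances = values.var(axis=0)
    for name, v in zip(cols, variances):
        if v == 0:
            warnings.warn(f"zero-variance column dropped: {name!r}")
            dropped.append(name)
    kept = [c for c in cols if c not in dropped]
    corr = X[kept].corr().to_numpy()
    alive = np.ones(len(kept), dtype=bool)
    for i in range(len(kept)):
        if not alive[i]:
            continue
        for j in range(i + 1, len(kept)):
            if alive[j] and abs(corr[i, j]) >= threshold:
                alive[j] = False
                dropped.append(kept[j])
    kept = [c for c, a in zip(kept, alive) if a]
    return X[kept], dropped, kept


def check_collinearity(
    lh: pd.DataFrame,
    threshold: float = 0.7,
    covariates: tuple[str, ...] = LIFE_HISTORY_COVARIATES,
) -> tuple[list[tuple[tuple[str, str], float]], list[str]]:
    """Report covariate pairs with ``|r| > threshold`` (pairwise-complete).

    Pairs are reported, not dropped — exclusion is an analyst decision.
    Covariates with fewer than three non-missing values (including constants,
    whose correlation is undefined) are flagged and excluded from testing.

    Returns ``(pairs, flagged)`` where pairs is ``[((a, b), r), ...]``.
    """
    present = [c for c in covariates if c in lh.columns]
    flagged = []
    usable = []
    for c in present:
        vals = lh[c].dropna()
        if len(vals) < 3 or vals.nunique() < 2:
            flagged.append(c)
        else:
            usable.append(c)
    pairs = []
    for i, a in enumerate(usable):
        for b in usable[i + 1 :]:
            sub = lh[[a, b]].dropna()
            if len(sub) < 3:
                continue
            r = sub[a].corr(sub[b])
            if np.isfinite(r) and abs(r) > threshold:
                pairs.append(((a, b), float(r)))
    return pairs, flagged


def read_life_history_table(path: str | Path) -> pd.DataFrame:
    """Read the per-population life-history table and check its invariants."""
    df = _read_delimited(path)
    for col in ("population", "species"):
        if col not in df.columns:
            raise FormatError(f"missing mandatory column: {col!r}")
    if df["population"].duplicated().any():
        raise ValidationError("life-history table must have one row per population")
    for col in ("epp", "male_provisioning", "male_survival"):
        if col in df.columns:
            vals = df[col].dropna()
            if ((vals < 0) | (vals > 1)).any():
                raise ValidationError(f"{col!r} must lie in [0, 1]")
    return df


def read_newick(path: str | Path, tol: float = 1e-6):
    """Read a Newick tree; report (not enforce) ultrametricity.

    Returns a :class:`dendropy.Tree` with ``tree.is_ultrametric`` (bool,
    relative tolerance ``tol`` on root-to-tip depths) attached.
    """
    tree = dendropy.Tree.get(path=str(path), schema="newick")
    depths = tip_depths(tree)
    vals = np.array(list(depths.values()))
    span = vals.max() - vals.min()
    tree.is_ultrametric = bool(span <= tol * max(vals.max(), 1e-300))
    for leaf in tree.leaf_node_iter():
        if leaf.edge.length is not None and leaf.edge.length == 0:
            warnings.warn(f"zero-length terminal branch at {leaf.taxon.label!r}")
    return tree


def tip_depths(tree: "dendropy.Tree") -> dict[str, float]:
    """Root-to-tip path length per tip label."""
    out = {}
    for leaf in tree.leaf_node_iter():
        d = 0.0
        node = leaf
        while node.parent_node is not None:
            d += node.edge.length or 0.0
            node = node.parent_node
        out[leaf.taxon.label] = d
    return out
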