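"""Reading, validation, filtering, intersection and imputation of beta-value matrices.

A *beta value* is the per-CpG methylation fraction in [0, 1] measured by an
Illumina array probe (1 = fully methylated, 0 = unmethylated).  Matrices come
as delimited text in the GEO series-matrix convention: loci as rows, first
column holding cg-prefixed probe IDs, header row holding sample IDs.  Empty
cells or "NA" (case-insensitive) denote missing measurements.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING_TOKENS = frozenset({"", "na"})
#: token written for masked cells
MISSING_OUT = "NA"


@dataclass
class BetaMatrix:
    """Samples x loci methylation fractions with an explicit missing-value mask.

    ``values[i, j]`` is the beta value of sample ``sample_ids[i]`` at locus
    ``locus_ids[j]``; entries where ``mask`` is True are treated as missing
    (the stored number there carries no meaning for analysis, though the
    synthetic generator keeps ground truth under the mask for scoring).
    """

    sample_ids: list[str]
    locus_ids: list[str]
    values: np.ndarray
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.mask is None:
            self.mask = ~np.isfinite(self.values)
        self.mask = np.asarray(self.mask, dtype=bool)
        n, p = len(self.sample_ids), len(self.locus_ids)
        if self.values.shape != (n, p) or self.mask.shape != (n, p):
            raise ValueError(
                f"shape mismatch: values {self.values.shape}, mask {self.mask.shape}, "
                f"expected ({n}, {p})"
            )
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample IDs")
        if len(set(self.locus_ids)) != p:
            raise ValueError("duplicate locus IDs")
        observed = self.values[~self.mask]
        if observed.size and (
            not np.all(np.isfinite(observed))
            or observed.min() < 0.0
            or observed.max() > 1.0
        ):
            bad = np.argwhere(~self.mask & ~((self.values >= 0) & (self.values <= 1)))
            i, j = bad[0]
            raise ValueError(
                f"beta value out of [0, 1] at sample {self.sample_ids[i]!r}, "
                f"locus {self.locus_ids[j]!r}: {self.values[i, j]}"
            )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)

    def missing_fraction_per_sample(self) -> np.ndarray:
        return self.mask.mean(axis=1)

    def copy(self) -> "BetaMatrix":
        return BetaMatrix(
            list(self.sample_ids), list(self.locus_ids),
            self.values.copy(), self.mask.copy(),
        )


@dataclass
class LocusPanel:
    """Ordered list of CpG IDs defining the model's input order and dimension."""

    locus_ids: list[str]

    def __post_init__(self) -> None:
        if not self.locus_ids:
            raise ValueError("locus panel is empty")
        if len(set(self.locus_ids)) != len(self.locus_ids):
            raise ValueError("duplicate locus IDs in panel")

    def __len__(self) -> int:
        return len(self.locus_ids)


def _detect_sep(path: str) -> str:
    with open(path) as fh:
        first = fh.readline()
    return "\t" if "\t" in first else ","


def read_beta_matrix(path, orientation: str = "loci_as_rows") -> BetaMatrix:
    """Read a delimited beta-value table.

    ``loci_as_rows`` (the GEO series-matrix convention) expects the first
    column to hold CpG IDs and the header row sample IDs;
    ``samples_as_rows`` is the transpose.  Empty cells and "NA"
    (case-insensitive) are read as missing.
    """
    if orientation not in ("loci_as_rows", "samples_as_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    sep = _detect_sep(str(path))
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)[1:]
    if len(set(header)) != len(header):  # pandas would silently mangle these
        raise ValueError(f"duplicate IDs in header of {path}")
    df = pd.read_csv(
        str(path), sep=sep, index_col=0, dtype=str,
        keep_default_na=False,
    )
    if orientation == "loci_as_rows":
        df = df.T  # -> samples x loci
    sample_ids = [str(s) for s in df.index]
    locus_ids = [str(c) for c in df.columns]
    if len(set(sample_ids)) != len(sample_ids):
        raise ValueError(f"duplicate sample IDs in {path}")
    if len(set(locus_ids)) != len(locus_ids):
        raise ValueError(f"duplicate locus IDs in {path}")
    raw = df.to_numpy(dtype=object)
    stripped = np.char.strip(raw.astype(str))
    mask = np.isin(np.char.lower(stripped), list(MISSING_TOKENS))
    values = np.full(raw.shape, np.nan)
    if (~mask).any():
        parsed = pd.to_numeric(pd.Series(stripped[~mask]), errors="coerce")
        bad = parsed.isna().to_numpy()
        if bad.any():
            rows, cols = np.nonzero(~mask)
            k = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"non-numeric cell {stripped[~mask][bad][0]!r} at sample "
                f"{sample_ids[rows[k]]!r}, locus {locus_ids[cols[k]]!r}"
            )
        values[~mask] = parsed.to_numpy(dtype=float)
    return BetaMatrix(sample_ids, locus_ids, values, mask)


def write_beta_matrix(bm: BetaMatrix, path, orientation: str = "loci_as_rows",
                      sep: str = "\t", float_format: str = "%.10g") -> None:
    """Write a beta matrix so that :func:`read_beta_matrix` reproduces it."""
    if orientation not in ("loci_as_rows", "samples_as_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    vals = bm.values.astype(object)
    formatted = np.empty(vals.shape, dtype=object)
    obs = ~bm.mask
    formatted[obs] = [float_format % v for v in bm.values[obs]]
    formatted[bm.mask] = MISSING_OUT
    df = pd.DataFrame(formatted, index=bm.sample_ids, columns=bm.locus_ids)
    if orientation == "loci_as_rows":
        df = df.T
        df.index.name = "ID_REF"
    else:
        df.index.name = "sample_id"
    df.to_csv(str(path), sep=sep)


def filter_samples_by_missingness(bm: BetaMatrix,
                                  max_missing_fraction: float = 0.5) -> BetaMatrix:
    """Drop samples with *strictly more* than ``max_missing_fraction`` missing.

    The default 0.5 is the standard "more than 50% of beta values missing"
    QC rule; a sample at exactly the threshold is retained.
    """
    keep = bm.missing_fraction_per_sample() <= max_missing_fraction
    return BetaMatrix(
        [s for s, k in zip(bm.sample_ids, keep) if k],
        list(bm.locus_ids),
        bm.values[keep].copy(),
        bm.mask[keep].copy(),
    )


def intersect_loci(bm: BetaMatrix, panel: LocusPanel) -> BetaMatrix:
    """Reorder/restrict columns to the panel; absent loci become fully missing."""
    pos = {l: j for j, l in enumerate(bm.locus_ids)}
    n, p = bm.n_samples, len(panel)
    values = np.full((n, p), np.nan)
    mask = np.ones((n, p), dtype=bool)
    absent = 0
    for j, locus in enumerate(panel.locus_ids):
        k = pos.get(locus)
        if k is None:
            absent += 1
            continue
        values[:, j] = bm.values[:, k]
        mask[:, j] = bm.mask[:, k]
    if p and absent / p > 0.10:
        logger.warning(
            "%d of %d panel loci (%.1f%%) absent from the beta matrix",
            absent, p, 100 * absent / p,
        )
    return BetaMatrix(list(bm.sample_ids), list(panel.locus_ids), values, mask)


def impute_missing(bm: BetaMatrix, max_predictors: int = 5) -> BetaMatrix:
    """Regression-based imputation of missing beta values.

    For each locus with missing entries, a least-squares linear model of that
    locus on its ``max_predictors`` most-correlated fully observed loci
    (correlation over samples where the target is observed) predicts the
    missing entries; predictions are clamped to [0, 1].  Falls back to the
    locus's observed mean when no regression is feasible, and to the global
    observed mean for loci missing in every sample.
    """
    if max_predictors < 1:
        raise ValueError("max_predictors must be >= 1")
    values = bm.values.copy()
    mask = bm.mask.copy()
    if not mask.any():
        return bm.copy()
    observed_any = bm.values[~bm.mask]
    global_mean = float(observed_any.mean()) if observed_any.size else 0.5
    complete = ~bm.mask.any(axis=0)  # fully observed loci: candidate predictors
    X_full = bm.values[:, complete] if complete.any() else None
    for j in np.flatnonzero(mask.any(axis=0)):
        miss = mask[:, j]
        obs = ~miss
        if not obs.any():
            logger.warning("locus %s missing in all samples; global-mean filled",
                           bm.locus_ids[j])
            values[miss, j] = global_mean
            mask[miss, j] = False
            continue
        y = bm.values[obs, j]
        pred = None
        if X_full is not None and obs.sum() >= 2:
            Xo = X_full[obs]
            sd = Xo.std(axis=0)
            yc = y - y.mean()
            ysd = yc.std()
            with np.errstate(invalid="ignore", divide="ignore"):
                corr = (Xo - Xo.mean(axis=0)).T @ yc / (len(y) * sd * ysd)
            corr = np.where(np.isfinite(corr), np.abs(corr), -1.0)
            if (corr > 0).any():
                top = np.argsort(-corr, kind="stable")[:max_predictors]
                A = np.column_stack([np.ones(obs.sum()), X_full[obs][:, top]])
                coef, *_ = np.linalg.lstsq(A, y, rcond=None)
                B = np.column_stack([np.ones(miss.sum()), X_full[miss][:, top]])
                pred = B @ coef
        if pred is None:
            pred = np.full(miss.sum(), y.mean())
        values[miss, j] = np.clip(pred, 0.0, 1.0)
        mask[miss, j] = False
    return BetaMatrix(list(bm.sample_ids), list(bm.locus_ids), values, mask)


# --- sample metadata -------------------------------------------------------

META_REQUIRED = ("sample_id", "age")
META_OPTIONAL = ("tissue", "platform", "dataset_id")


def read_sample_meta(path) -> pd.DataFrame:
    """Read a per-sample metadata table (sample_id, age[, tissue, platform, dataset_id])."""
    df = pd.read_csv(str(path), sep=_detect_sep(str(path)))
    return validate_sample_meta(df)


def validate_sample_meta(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    for col in META_REQUIRED:
        if col not in df.columns:
            raise ValueError(f"metadata missing required column {col!r}")
    df["sample_id"] = df["sample_id"].astype(str)
    if df["sample_id"].duplicated().any():
        dup = df["sample_id"][df["sample_id"].duplicated()].iloc[0]
        raise ValueError(f"duplicate sample_id in metadata: {dup!r}")
    df["age"] = pd.to_numeric(df["age"])
    if (df["age"] < 0).any() or df["age"].isna().any():
        raise ValueError("ages must be non-negative finite numbers")
    for col in META_OPTIONAL:
        if col not in df.columns:
            df[col] = "unknown"
        df[col] = df[col].astype(str)
    return df[list(META_REQUIRED) + list(META_OPTIONAL)]


def write_sample_meta(df: pd.DataFrame, path, sep: str = "\t") -> None:
    validate_sample_meta(df).to_csv(str(path), sep=sep, index=False)


def read_locus_panel(path) -> LocusPanel:
    """Read a locus panel: one CpG ID per line, blank lines ignored."""
    with open(path) as fh:
        ids = [line.strip() for line in fh if line.strip()]
    return LocusPanel(ids)


def write_locus_panel(panel: LocusPanel, path) -> None:
    with open(path, "w") as fh:
        fh.write("\n".join(panel.locus_ids) + "\n")
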