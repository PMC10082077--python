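"""Untargeted LC-MS peak-table preprocessing.

The chain applied to each study is: blank/fill/signal-to-noise/detection
filtering -> QC-based robust LOESS drift correction (QC-RLSC) -> batch
concatenation by identification, adduct, m/z and retention-time tolerance
-> quantile normalization (Bolstad).  Each stage consumes and returns a
:class:`PeakTable` so stages can be run and inspected independently.

Zeros in the intensity matrix mark undetected peaks; "detected" always
means intensity > 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

SAMPLE_CLASSES = ("sample", "QC", "blank")

FEATURE_META_COLUMNS = ["mz", "rt", "adduct", "identification"]
SAMPLE_META_COLUMNS = ["batch", "injection_order", "class", "strain", "phase"]


@dataclass
class PeakTable:
    """Features x samples intensity matrix with the two metadata tables.

    ``intensities``: DataFrame indexed by feature_id with sample_id
    columns, nonnegative, 0 = not detected.
    ``feature_meta``: indexed by feature_id with columns mz (Da), rt
    (min), adduct, identification.
    ``sample_meta``: indexed by sample_id with columns batch,
    injection_order, class ("sample"/"QC"/"blank"), strain, phase.
    """

    intensities: pd.DataFrame
    feature_meta: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self):
        if not self.intensities.index.equals(self.feature_meta.index):
            raise ValueError("feature metadata index does not match intensity rows")
        if not self.intensities.columns.equals(self.sample_meta.index):
            raise ValueError("sample metadata index does not match intensity columns")
        bad = set(self.sample_meta["class"]) - set(SAMPLE_CLASSES)
        if bad:
            raise ValueError(f"unknown sample classes: {sorted(bad)}")
        dup = self.sample_meta.groupby("batch")["injection_order"].apply(
            lambda s: s.duplicated().any())
        if dup.any():
            raise ValueError("injection_order must be unique within each batch")

    @property
    def n_features(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[1]

    def samples_of_class(self, cls: str) -> pd.Index:
        return self.sample_meta.index[self.sample_meta["class"] == cls]

    def subset_features(self, feature_ids) -> "PeakTable":
        return PeakTable(
            intensities=self.intensities.loc[feature_ids],
            feature_meta=self.feature_meta.loc[feature_ids],
            sample_meta=self.sample_meta,
        )

    def subset_samples(self, sample_ids) -> "PeakTable":
        return PeakTable(
            intensities=self.intensities[sample_ids],
            feature_meta=self.feature_meta,
            sample_meta=self.sample_meta.loc[sample_ids],
        )

    def copy(self) -> "PeakTable":
        return PeakTable(self.intensities.copy(), self.feature_meta.copy(),
                         self.sample_meta.copy())

    # -- CSV interface: intensity matrix + two metadata files ------------
    def to_csv(self, intensity_path, feature_meta_path, sample_meta_path) -> None:
        self.intensities.rename_axis("feature_id").to_csv(intensity_path)
        self.feature_meta.rename_axis("feature_id").to_csv(feature_meta_path)
        self.sample_meta.rename_axis("sample_id").to_csv(sample_meta_path)

    @classmethod
    def from_csv(cls, intensity_path, feature_meta_path, sample_meta_path) -> "PeakTable":
        inten = pd.read_csv(intensity_path, index_col="feature_id")
        fmeta = pd.read_csv(feature_meta_path, index_col="feature_id")
        smeta = pd.read_csv(sample_meta_path, index_col="sample_id")
        return cls(inten, fmeta, smeta)


# ---------------------------------------------------------------------------
# Filtering


@dataclass
class FilterLog:
    """Per-feature record of which removal rule fired, if any."""

    records: pd.DataFrame  # columns: feature_id, removed, rule
    counts: dict = field(default_factory=dict)


def filter_peaks(
    table: PeakTable,
    blank_rule: bool = True,
    fill_threshold: float = 0.1,
    sn_threshold: float = 10.0,
    detection_fraction: float = 2.0 / 3.0,
    detection_any_batch: bool = True,
) -> tuple[PeakTable, FilterLog]:
    """Remove low-quality features by the four study rules.

    A feature is removed if any of these fires (checked in this order, the
    log records the first rule that fired):

    1. ``blank``: its mean over study samples does not exceed its mean
       over blanks (identified contaminant / background).
    2. ``fill``: fraction of study samples in which it was detected
       (intensity > 0) is below ``fill_threshold``.
    3. ``sn``: signal-to-noise below ``sn_threshold``.  An ``sn`` column
       in the feature metadata (instrument-reported) is used when
       present; otherwise S/N = mean(study samples)/mean(blanks).
    4. ``detection``: detected in fewer than ``detection_fraction`` of
       study samples in every batch (kept iff it reaches the fraction in
       at least one batch).  ``detection_any_batch=False`` flips to the
       stricter reading: must reach the fraction in every batch.
    """
    study = table.samples_of_class("sample")
    blanks = table.samples_of_class("blank")
    if blank_rule and len(blanks) == 0:
        raise ValueError("blank_rule enabled but the table contains no blank samples")

    X = table.intensities
    study_mean = X[study].mean(axis=1)
    detected = X[study] > 0
    fill = detected.mean(axis=1)

    if "sn" in table.feature_meta.columns:
        sn = table.feature_meta["sn"].astype(float)
    else:
        if len(blanks) == 0:
            raise ValueError("no S/N metadata and no blanks to compute S/N from")
        blank_mean = X[blanks].mean(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            sn = study_mean / blank_mean.replace(0.0, np.nan)
        sn = sn.fillna(np.inf)

    batches = table.sample_meta.loc[study, "batch"]
    per_batch_det = detected.T.groupby(batches).mean().T  # features x batches
    if detection_any_batch:
        detection_ok = (per_batch_det >= detection_fraction).any(axis=1)
    else:
        detection_ok = (per_batch_det >= detection_fraction).all(axis=1)

    # removal is the union of the rules; the log attributes each removed
    # feature to the first firing rule (fill before blank, so an
    # undetected feature is reported as a fill failure, not a blank one)
    rules = pd.Series("", index=X.index, dtype=object)
    rules[(fill < fill_threshold) & (rules == "")] = "fill"
    if blank_rule:
        blank_mean = X[blanks].mean(axis=1)
        fired = study_mean <= blank_mean
        rules[fired & (rules == "")] = "blank"
    rules[(sn < sn_threshold) & (rules == "")] = "sn"
    rules[(~detection_ok) & (rules == "")] = "detection"

    removed = rules != ""
    log = FilterLog(
        records=pd.DataFrame({"removed": removed, "rule": rules}).rename_axis("feature_id"),
        counts={"in": int(len(rules)), "out": int((~removed).sum()),
                **rules[removed].value_counts().to_dict()},
    )
    return table.subset_features(X.index[~removed]), log


# ---------------------------------------------------------------------------
# QC-RLSC drift correction


def qc_rlsc(table: PeakTable, loess_span: float = 0.75,
            min_qc_for_loess: int = 4) -> PeakTable:
    """QC-sample-based robust LOESS signal correction, per batch per feature.

    A robust local linear regression (tricube weights, iterated
    reweighting) of QC intensity against injection order gives the drift
    curve; each sample's intensity is divided by (fitted drift at its
    injection order) / (median QC intensity).  Batches with fewer than
    ``min_qc_for_loess`` detected QC values for a feature fall back to
    constant median scaling; features whose QC values are all zero in a
    batch pass through unchanged with a warning.
    """
    if not (0 < loess_span <= 1):
        raise ValueError("loess_span must be in (0, 1]")
    out = table.copy()
    X = out.intensities
    meta = out.sample_meta
    n_batch_qc = meta[meta["class"] == "QC"].groupby("batch").size()
    if (n_batch_qc < 2).any() or n_batch_qc.reindex(meta["batch"].unique()).isna().any():
        raise ValueError("QC-RLSC requires >= 2 QC samples in every batch")

    silent = 0
    for batch, batch_meta in meta.groupby("batch", sort=False):
        order = batch_meta["injection_order"].astype(float)
        qc_ids = batch_meta.index[batch_meta["class"] == "QC"]
        corr_ids = batch_meta.index[batch_meta["class"] != "blank"]
        qc_x = order[qc_ids].to_numpy()
        for fid in X.index:
            qc_y = X.loc[fid, qc_ids].to_numpy(dtype=float)
            pos = qc_y > 0
            if pos.sum() == 0:
                silent += 1
                continue
            med = float(np.median(qc_y[pos]))
            if pos.sum() >= min_qc_for_loess:
                fit = lowess(qc_y[pos], qc_x[pos], frac=loess_span, it=3,
                             return_sorted=True)
                drift = np.interp(order[corr_ids].to_numpy(), fit[:, 0], fit[:, 1])
            else:
                drift = np.full(len(corr_ids), med)
            factor = drift / med
            factor = np.where(factor > 1e-6, factor, 1.0)
            X.loc[fid, corr_ids] = X.loc[fid, corr_ids].to_numpy() / factor
    if silent:
        warnings.warn(f"{silent} feature/batch combinations had all-zero QCs; left uncorrected")
    return out


# ---------------------------------------------------------------------------
# Batch alignment


def align_batches(tables: list[PeakTable], mz_tol: float = 0.01,
                  rt_tol: float = 0.75) -> PeakTable:
    """Concatenate per-batch tables, merging features across batches.

    Two features merge iff their identification labels match, their
    adducts match, |dm/z| <= ``mz_tol`` (Da) and |dRT| <= ``rt_tol``
    (min).  Matching is greedy nearest-m/z, processing features in
    ascending m/z for a deterministic, batch-order-independent result.
    Features with no partner stay as batch-specific rows, zero-filled for
    the other batches' samples.
    """
    if len(tables) < 2:
        raise ValueError("align_batches needs at least 2 tables")
    all_samples = pd.Index([s for t in tables for s in t.intensities.columns])
    if all_samples.has_duplicates:
        raise ValueError("duplicate sample_ids across batches")

    # pool every (table, feature) pair, sorted by m/z then id for determinism
    entries = []
    for ti, t in enumerate(tables):
        for fid in t.intensities.index:
            fm = t.feature_meta.loc[fid]
            entries.append((float(fm["mz"]), str(fid), ti, fid, fm))
    entries.sort(key=lambda e: (e[0], e[1], e[2]))

    clusters: list[dict] = []  # each: {"meta": fm, "members": {table_idx: fid}}
    for mz, _, ti, fid, fm in entries:
        best = None
        best_dmz = None
        for c in clusters:
            cm = c["meta"]
            if ti in c["members"]:
                continue  # one feature per batch per cluster
            if cm["identification"] != fm["identification"] or cm["adduct"] != fm["adduct"]:
                continue
            dmz = abs(cm["mz"] - mz)
            if dmz > mz_tol or abs(cm["rt"] - fm["rt"]) > rt_tol:
                continue
            if best is None or dmz < best_dmz:
                best, best_dmz = c, dmz
        if best is None:
            clusters.append({"meta": fm.copy(), "members": {ti: fid}})
        else:
            best["members"][ti] = fid

    rows, fmeta_rows, fids = [], [], []
    for c in clusters:
        member_ids = [f"b{ti}:{fid}" for ti, fid in sorted(c["members"].items())]
        # keep the first member's id when unambiguous, else a merged id
        first_fid = c["members"][min(c["members"])]
        fid_out = str(first_fid)
        if fid_out in fids:
            fid_out = "|".join(member_ids)
        row = pd.Series(0.0, index=all_samples)
        for ti, fid in c["members"].items():
            row[tables[ti].intensities.columns] = tables[ti].intensities.loc[fid].to_numpy()
        rows.append(row)
        fmeta_rows.append(c["meta"])
        fids.append(fid_out)

    intens = pd.DataFrame(rows, index=pd.Index(fids, name="feature_id"))
    fmeta = pd.DataFrame(fmeta_rows, index=intens.index)
    smeta = pd.concat([t.sample_meta for t in tables])
    return PeakTable(intens, fmeta, smeta)


# ---------------------------------------------------------------------------
# Quantile normalization


def quantile_normalize(table: PeakTable, classes: tuple[str, ...] = ("sample", "QC")) -> PeakTable:
    """Quantile normalization of sample columns (Bolstad algorithm).

    Sort each column, average across columns at each rank, then assign
    the rank means back through each column's original ordering.  Tied
    values within a column receive the mean of their ranks' means.  Only
    columns of the listed classes are normalized; blanks pass through.
    """
    cols = table.sample_meta.index[table.sample_meta["class"].isin(classes)]
    if len(cols) < 2:
        raise ValueError("quantile normalization needs >= 2 samples")
    X = table.intensities[cols].to_numpy(dtype=float)
    normalized = quantile_normalize_matrix(X)
    out = table.copy()
    out.intensities.loc[:, cols] = normalized
    return out


def quantile_normalize_matrix(X: np.ndarray) -> np.ndarray:
    """Bolstad quantile normalization on a features x samples array."""
    n, m = X.shape
    order = np.argsort(X, axis=0, kind="stable")
    sorted_vals = np.take_along_axis(X, order, axis=0)
    rank_means = sorted_vals.mean(axis=1)
    out = np.empty_like(X)
    ranks = np.empty_like(order)
    np.put_along_axis(ranks, order, np.arange(n)[:, None], axis=0)
    for j in range(m):
        col = rank_means[ranks[:, j]]
        # average rank-means over ties within the column
        vals, inv = np.unique(X[:, j], return_inverse=True)
        if len(vals) < n:
            sums = np.bincount(inv, weights=col)
            counts = np.bincount(inv)
            col = (sums / counts)[inv]
        out[:, j] = col
    return out


# ---------------------------------------------------------------------------
# Full chain


def preprocess(
    tables: list[PeakTable],
    blank_rule: bool = True,
    fill_threshold: float = 0.1,
    sn_threshold: float = 10.0,
    detection_fraction: float = 2.0 / 3.0,
    loess_span: float = 0.75,
    mz_tol: float = 0.01,
    rt_tol: float = 0.75,
) -> tuple[PeakTable, list[FilterLog]]:
    """filter -> QC-RLSC -> align -> quantile-normalize, per-batch inputs.

    ``tables`` holds one PeakTable per experimental batch.  Filtering and
    drift correction run per batch; alignment concatenates; quantile
    normalization runs on the concatenated table.
    """
    logs = []
    corrected = []
    for t in tables:
        filtered, log = filter_peaks(t, blank_rule=blank_rule,
                                     fill_threshold=fill_threshold,
                                     sn_threshold=sn_threshold,
                                     detection_fraction=detection_fraction)
        logs.append(log)
        corrected.append(qc_rlsc(filtered, loess_span=loess_span))
    if len(corrected) > 1:
        merged = align_batches(corrected, mz_tol=mz_tol, rt_tol=rt_tol)
    else:
        merged = corrected[0]
    return quantile_normalize(merged), logs
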