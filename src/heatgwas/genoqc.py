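"""Marker quality control for the dosage matrix.

Two filters mirror standard SNP-chip QC for this kind of study: markers with
minor allele frequency strictly below a threshold (default 5%) are removed
(MAF exactly equal to the threshold survives), and markers without a unique
(chromosome, position) on the map are removed — both members of a duplicated
position are dropped, since uniqueness is a property of the marker, not of
file order.  Remaining missing dosages are filled with the marker's mean
dosage over non-missing animals; the downstream sampler accepts continuous
dosages, so no rounding is applied.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin


def compute_maf(dosages: pd.DataFrame) -> pd.Series:
    """Minor allele frequency per marker from non-missing dosages in {0,1,2}.

    Markers with all genotypes missing get NaN.
    """
    freq = dosages.mean(axis=0, skipna=True) / 2.0
    return np.minimum(freq, 1.0 - freq)


def maf_filter(
    dosages: pd.DataFrame, threshold: float = 0.05
) -> tuple[list[str], pd.DataFrame]:
    """Remove markers with MAF strictly below ``threshold``.

    Parameters
    ----------
    dosages : DataFrame
        Animals x markers, values in {0, 1, 2} or NaN for missing.
    threshold : float
        Markers with MAF < threshold are removed; MAF == threshold is kept.

    Returns
    -------
    (kept_markers, report)
        ``kept_markers`` is the list of surviving marker ids in input order;
        ``report`` has one row per marker with columns ``marker_id``, ``maf``,
        ``n_called``, ``status`` in {kept, removed_low_maf, removed_all_missing}.
    """
    maf = compute_maf(dosages)
    n_called = dosages.notna().sum(axis=0)
    status = np.where(
        n_called == 0,
        "removed_all_missing",
        np.where(maf < threshold, "removed_low_maf", "kept"),
    )
    report = pd.DataFrame({
        "marker_id": dosages.columns,
        "maf": maf.to_numpy(),
        "n_called": n_called.to_numpy(),
        "status": status,
    })
    kept = report.loc[report["status"] == "kept", "marker_id"].tolist()
    return kept, report


def map_filter(marker_map: pd.DataFrame) -> list[str]:
    """Keep only markers with a known, unique (chromosome, position).

    Markers with a missing position are removed, and *all* markers sharing a
    (chromosome, position_bp) with another marker are removed.
    """
    m = marker_map.copy()
    known = m["position_bp"].notna() & m["chromosome"].notna()
    dup = m.duplicated(subset=["chromosome", "position_bp"], keep=False)
    keep = known & ~dup
    return m.loc[keep, "marker_id"].tolist()


def fill_missing(dosages: pd.DataFrame) -> pd.DataFrame:
    """Replace missing dosages by the marker's mean dosage (continuous fill).

    Column means are preserved.  Markers that are entirely missing must have
    been removed beforehand (see :func:`maf_filter`).
    """
    if dosages.isna().all(axis=0).any():
        raise ValueError("matrix contains all-missing markers; run maf_filter first")
    return dosages.fillna(dosages.mean(axis=0))


class GenotypeQC(BaseEstimator, TransformerMixin):
    """Transformer bundling MAF filtering, map filtering and mean-dosage fill.

    Parameters
    ----------
    maf_threshold : float, default 0.05
        Markers with MAF strictly below this are removed.
    marker_map : DataFrame or None
        Optional map with columns ``marker_id``, ``chromosome``,
        ``position_bp``; when given, markers lacking a unique map position
        are also removed.

    Attributes
    ----------
    kept_markers_ : list of str
        Markers surviving all filters, in input order.
    report_ : DataFrame
        Per-marker MAF-filter report (see :func:`maf_filter`).
    """

    def __init__(self, maf_threshold: float = 0.05, marker_map: pd.DataFrame | None = None):
        self.maf_threshold = maf_threshold
        self.marker_map = marker_map

    def fit(self, X: pd.DataFrame, y=None):
        kept, report = maf_filter(X, self.maf_threshold)
        if self.marker_map is not None:
            mappable = set(map_filter(self.marker_map))
            kept = [m for m in kept if m in mappable]
        self.kept_markers_ = kept
        self.report_ = report
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return fill_missing(X[self.kept_markers_])
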