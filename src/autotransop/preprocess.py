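"""Input filtering, transformations and cross-system pairing.

Implements the quality filters used for L1000-style perturbation signatures
(replicate counts, QC pass rates, outlier flags, TAS threshold, exemplar
selection), the count and serology transformations, and construction of the
pairing index that links samples sharing an experimental condition across the
two biological systems.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.io import mmread, mmwrite
from scipy.sparse import coo_matrix

__all__ = [
    "ConditionKey",
    "SampleRecord",
    "OmicsDataset",
    "PairIndex",
    "filter_l1000",
    "log_transform_counts",
    "preprocess_serology",
    "build_pair_index",
    "batch_mask",
    "read_dataset",
    "write_dataset",
]


def _norm(s: str) -> str:
    return " ".join(str(s).strip().lower().split())


@dataclass(frozen=True)
class ConditionKey:
    """Experimental condition identity: perturbagen + dose + time.

    For disease/serology study modes the three slots hold diagnosis /
    protection / vaccination labels instead.  Equality is exact tuple equality
    after whitespace and case normalization, so keys are comparable across
    systems; no dose-unit conversion is attempted.
    """

    perturbagen: str
    dose: str = ""
    time: str = ""

    def __post_init__(self):
        object.__setattr__(self, "perturbagen", _norm(self.perturbagen))
        object.__setattr__(self, "dose", _norm(self.dose))
        object.__setattr__(self, "time", _norm(self.time))

    def as_tuple(self) -> tuple[str, str, str]:
        return (self.perturbagen, self.dose, self.time)


@dataclass
class SampleRecord:
    """One signature with the metadata the quality filters need."""

    sample_id: str
    system: str
    condition: ConditionKey
    values: Optional[np.ndarray] = None
    n_replicates: int = 1
    n_passed_qc: int = 1
    is_outlier: bool = False
    tas: Optional[float] = None
    is_exemplar: Optional[bool] = None
    protection: Optional[str] = None
    vaccination: Optional[str] = None
    celltype: Optional[str] = None


@dataclass
class OmicsDataset:
    """Sample x feature matrix with per-sample metadata.

    mode is one of ``zscore`` (continuous differential-expression profiles),
    ``count`` (non-negative integer counts) or ``serology`` (continuous
    antibody/receptor features paired by protection status).
    """

    matrix: np.ndarray
    samples: list[SampleRecord]
    feature_ids: list[str]
    mode: str = "zscore"

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix)
        if self.matrix.shape[0] != len(self.samples):
            raise ValueError("matrix rows must match number of sample records")
        if self.matrix.shape[1] != len(self.feature_ids):
            raise ValueError("matrix columns must match number of feature ids")
        if np.isnan(self.matrix.astype(float)).any():
            raise ValueError("dataset contains missing values")
        if self.mode == "count":
            m = self.matrix
            if (m < 0).any() or not np.allclose(m, np.round(m)):
                raise ValueError("count mode requires non-negative integer entries")

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]

    @property
    def systems(self) -> list[str]:
        return sorted({s.system for s in self.samples})

    def system_of(self, i: int) -> str:
        return self.samples[i].system

    def obs_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.samples:
            rows.append({
                "sample_id": s.sample_id, "system": s.system,
                "perturbagen": s.condition.perturbagen, "dose": s.condition.dose,
                "time": s.condition.time, "n_replicates": s.n_replicates,
                "n_passed_qc": s.n_passed_qc, "is_outlier": s.is_outlier,
                "tas": np.nan if s.tas is None else s.tas,
                "protection": s.protection, "vaccination": s.vaccination,
                "celltype": s.celltype,
            })
        return pd.DataFrame(rows).set_index("sample_id")

    def to_anndata(self):
        """Optional AnnData view (anndata is not a hard dependency)."""
        import anndata

        return anndata.AnnData(X=self.matrix.astype(float), obs=self.obs_frame(),
                               var=pd.DataFrame(index=self.feature_ids))


@dataclass
class PairIndex:
    """Positive pairs linking samples that share a condition across systems.

    ``positive_pairs`` indexes into the concatenated sample list the index was
    built over; ``batch_mask`` materializes the per-batch square binary mask
    (symmetric, zero diagonal) used by the mutual-information and alignment
    losses.
    """

    positive_pairs: list[tuple[int, int]]
    n_samples: int

    def mask(self, batch_indices: Optional[Sequence[int]] = None) -> np.ndarray:
        if batch_indices is None:
            batch_indices = range(self.n_samples)
        return batch_mask(self.positive_pairs, list(batch_indices))


def batch_mask(positive_pairs: Sequence[tuple[int, int]], batch_indices: Sequence[int]) -> np.ndarray:
    """Square binary mask of positives over the given batch (symmetric, zero diagonal)."""
    pos = set()
    for a, b in positive_pairs:
        pos.add((a, b))
        pos.add((b, a))
    n = len(batch_indices)
    mask = np.zeros((n, n), dtype=float)
    for i, gi in enumerate(batch_indices):
        for j, gj in enumerate(batch_indices):
            if i != j and (gi, gj) in pos:
                mask[i, j] = 1.0
    return mask


# ---------------------------------------------------------------------------
# L1000-style quality filtering
# ---------------------------------------------------------------------------

def filter_l1000(records: list[SampleRecord], tas_threshold: float = 0.3, *,
                 min_replicates: int = 4, qc_fraction: float = 0.5,
                 control_mode: bool = False) -> list[SampleRecord]:
    """Retain high-quality signatures.

    A record is kept when it has at least ``min_replicates`` replicates ("more
    than three"), at least ``ceil(qc_fraction * n_replicates)`` of them passed
    QC, it is not flagged as a statistical outlier, and its transcriptional
    activity score (TAS) is >= ``tas_threshold`` (inclusive).  Among technical
    replicates of the same perturbagen/condition within one system only the
    max-TAS exemplar is retained.  Input order is preserved; the operation is
    idempotent.  Control signatures (``control_mode=True``) skip the TAS
    threshold but still require the TAS field for exemplar selection when
    present in duplicated conditions.
    """
    kept: list[SampleRecord] = []
    for r in records:
        if r.tas is None and not control_mode:
            raise ValueError(f"sample {r.sample_id!r} is missing the TAS field")
        if r.is_outlier:
            continue
        if r.n_replicates < min_replicates:
            continue
        if r.n_passed_qc < math.ceil(qc_fraction * r.n_replicates):
            continue
        if not control_mode and r.tas < tas_threshold:
            continue
        kept.append(r)

    # exemplar selection: max TAS per (system, condition)
    best: dict[tuple[str, tuple[str, str, str]], SampleRecord] = {}
    for r in kept:
        key = (r.system, r.condition.as_tuple())
        tas = -np.inf if r.tas is None else r.tas
        cur = best.get(key)
        cur_tas = -np.inf if (cur is None or cur.tas is None) else cur.tas
        if cur is None or tas > cur_tas:
            best[key] = r
    chosen = {id(r) for r in best.values()}
    return [r for r in kept if id(r) in chosen]


def log_transform_counts(x) -> np.ndarray:
    """Elementwise log10(count + 1); errors on negative entries."""
    x = np.asarray(x, dtype=float)
    if (x < 0).any():
        raise ValueError("counts must be non-negative for the log transform")
    return np.log10(x + 1.0)


def _zscore_columns(x: np.ndarray, fit_rows=None) -> np.ndarray:
    ref = x if fit_rows is None else x[np.asarray(fit_rows, dtype=int)]
    sd = ref.std(axis=0, ddof=0)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        raise ValueError(f"zero-variance feature(s) at column index {zero.tolist()}")
    return (x - ref.mean(axis=0)) / sd


def preprocess_serology(data, controls=None, mode: str = "human",
                        fit_rows=None) -> np.ndarray:
    """Serology feature standardization.

    human mode: per-feature z-score of the raw panel.  nhp mode: log10(MFI+1),
    subtract the per-feature median of the (equally transformed) controls,
    then per-feature z-score.  By default the z-score statistics are computed
    over the full dataset (the global preprocessing convention); passing
    ``fit_rows`` restricts mean/sd estimation to those rows (e.g. a training
    split) for leakage-safe workflows, in which case only those rows are
    guaranteed mean 0 / sd 1.
    """
    data = np.asarray(data, dtype=float)
    if mode == "human":
        return _zscore_columns(data, fit_rows)
    if mode == "nhp":
        if controls is None:
            raise ValueError("nhp mode requires a control matrix")
        controls = np.asarray(controls, dtype=float)
        if controls.shape[1] != data.shape[1]:
            raise ValueError("controls must have the same features as the data")
        logged = log_transform_counts(data)
        ctrl_median = np.median(log_transform_counts(controls), axis=0)
        return _zscore_columns(logged - ctrl_median, fit_rows)
    raise ValueError(f"unknown serology mode {mode!r}")


# ---------------------------------------------------------------------------
# Pairing index
# ---------------------------------------------------------------------------

def build_pair_index(dataset: OmicsDataset) -> PairIndex:
    """Enumerate all positive pairs in a (possibly concatenated) dataset.

    In zscore/count mode a pair is positive iff the two samples share a
    ConditionKey and come from different systems.  In serology mode a pair is
    positive iff the two samples share protection status, regardless of
    species.
    """
    pairs: list[tuple[int, int]] = []
    n = dataset.n_samples
    if dataset.mode == "serology":
        for i in range(n):
            for j in range(i + 1, n):
                si, sj = dataset.samples[i], dataset.samples[j]
                if si.protection is not None and si.protection == sj.protection:
                    pairs.append((i, j))
    else:
        by_key: dict[tuple, list[int]] = {}
        for i, s in enumerate(dataset.samples):
            by_key.setdefault(s.condition.as_tuple(), []).append(i)
        for idxs in by_key.values():
            for a in range(len(idxs)):
                for b in range(a + 1, len(idxs)):
                    i, j = idxs[a], idxs[b]
                    if dataset.samples[i].system != dataset.samples[j].system:
                        pairs.append((i, j))
    return PairIndex(positive_pairs=pairs, n_samples=n)


def combine_datasets(ds_a: OmicsDataset, ds_b: OmicsDataset) -> OmicsDataset:
    """Stack two systems' datasets sample-wise for pairing.

    Feature spaces may differ; the combined matrix is block-padded with zeros
    and only used for metadata-level pairing, never for modeling.
    """
    pa, pb = ds_a.n_features, ds_b.n_features
    mat = np.zeros((ds_a.n_samples + ds_b.n_samples, pa + pb))
    mat[: ds_a.n_samples, :pa] = ds_a.matrix
    mat[ds_a.n_samples:, pa:] = ds_b.matrix
    feats = [f"A::{f}" for f in ds_a.feature_ids] + [f"B::{f}" for f in ds_b.feature_ids]
    return OmicsDataset(matrix=mat, samples=list(ds_a.samples) + list(ds_b.samples),
                        feature_ids=feats, mode=ds_a.mode)


# ---------------------------------------------------------------------------
# Readers / writers: delimited matrix + metadata sidecar, matrix-market counts
# ---------------------------------------------------------------------------

_META_COLS = ["system", "perturbagen", "dose", "time", "n_replicates", "n_passed_qc",
              "is_outlier", "tas", "protection", "vaccination", "celltype"]


def write_dataset(ds: OmicsDataset, prefix: str | Path, sparse: bool = False) -> None:
    """Write ``<prefix>.matrix.{tsv,mtx}``, ``<prefix>.meta.tsv`` and ``<prefix>.features.tsv``."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    if sparse:
        mmwrite(str(prefix) + ".matrix.mtx", coo_matrix(ds.matrix))
    else:
        pd.DataFrame(ds.matrix, index=[s.sample_id for s in ds.samples],
                     columns=ds.feature_ids).to_csv(str(prefix) + ".matrix.tsv", sep="\t")
    meta = ds.obs_frame()
    meta["mode"] = ds.mode
    meta.to_csv(str(prefix) + ".meta.tsv", sep="\t")
    pd.Series(ds.feature_ids, name="feature_id").to_csv(str(prefix) + ".features.tsv",
                                                        sep="\t", index=False)


def read_dataset(prefix: str | Path) -> OmicsDataset:
    prefix = Path(prefix)
    meta = pd.read_csv(str(prefix) + ".meta.tsv", sep="\t", index_col=0,
                       keep_default_na=True)
    feats = pd.read_csv(str(prefix) + ".features.tsv", sep="\t")["feature_id"].astype(str).tolist()
    mtx_tsv = Path(str(prefix) + ".matrix.tsv")
    if mtx_tsv.exists():
        mat = pd.read_csv(mtx_tsv, sep="\t", index_col=0).to_numpy()
    else:
        mat = np.asarray(mmread(str(prefix) + ".matrix.mtx").todense())
    mode = str(meta["mode"].iloc[0]) if "mode" in meta else "zscore"
    if mode == "count":
        mat = np.round(mat).astype(int)
    samples = []
    for sid, row in meta.iterrows():
        def _opt(col):
            v = row.get(col)
            return None if (v is None or (isinstance(v, float) and np.isnan(v))) else v
        samples.append(SampleRecord(
            sample_id=str(sid), system=str(row["system"]),
            condition=ConditionKey(str(row.get("perturbagen", "")),
                                   str(_opt("dose") or ""), str(_opt("time") or "")),
            n_replicates=int(row.get("n_replicates", 1)),
            n_passed_qc=int(row.get("n_passed_qc", 1)),
            is_outlier=bool(row.get("is_outlier", False)),
            tas=None if _opt("tas") is None else float(row["tas"]),
            protection=_opt("protection"), vaccination=_opt("vaccination"),
            celltype=_opt("celltype")))
    return OmicsDataset(matrix=mat, samples=samples, feature_ids=feats, mode=mode)
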