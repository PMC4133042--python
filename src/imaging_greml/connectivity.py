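"""Condition-specific functional connectivity from block-design ROI series.

From a 160-volume run the analysis takes, per condition, the blocks of that
condition (shifted 2 TRs into the hemodynamic response), mean-centers each
block, concatenates them together with the control blocks, correlates every
ROI pair, thresholds at r > 0.3 into an undirected graph and summarizes each
node by its degree.  The per-ROI phenotype is a simplified percent BOLD
signal change: the condition-vs-control contrast of shifted block means,
normalized by the whole-run mean signal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .config import BLOCK_LEN, CONDITIONS, REST_LABEL, TR_SECONDS
from .exceptions import ConfigError, DesignError


@dataclass
class RoiTimeSeries:
    """One subject's run: signal matrix (volumes x channels) plus design.

    Channels are the ROI columns plus the nuisance channels ``WM`` and
    ``CSF``.  ``design`` holds one block label per volume
    (ambiguous / angry / control / rest).
    """

    subject: str
    frame: pd.DataFrame
    design: np.ndarray
    tr_seconds: float = TR_SECONDS
    truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.design = np.asarray(self.design, dtype=object)
        if len(self.frame) != self.design.size:
            raise DesignError(
                f"{len(self.frame)} volumes but {self.design.size} design labels"
            )
        bad = set(self.design) - set(CONDITIONS) - {REST_LABEL}
        if bad:
            raise DesignError(f"unknown design labels: {sorted(bad)}")

    @property
    def n_volumes(self) -> int:
        return len(self.frame)

    @property
    def roi_names(self) -> list[str]:
        return [c for c in self.frame.columns if c not in ("WM", "CSF")]


@dataclass
class ConnectivityGraph:
    """Correlation matrix, thresholded adjacency and nodal degree."""

    condition: str
    corr: pd.DataFrame
    adjacency: np.ndarray
    degree: pd.Series

    def to_networkx(self) -> nx.Graph:
        G = nx.from_numpy_array(self.adjacency.astype(int))
        nx.relabel_nodes(
            G, dict(enumerate(self.corr.columns)), copy=False
        )
        return G


def _blocks(design: np.ndarray, condition: str) -> list[int]:
    """Start indices of contiguous runs of ``condition`` in the design."""
    lab = np.asarray(design, dtype=object)
    hits = np.flatnonzero(lab == condition)
    if hits.size == 0:
        return []
    starts = [int(hits[0])]
    for a, b in zip(hits[:-1], hits[1:]):
        if b != a + 1:
            starts.append(int(b))
    return starts


def regress_nuisance(ts: RoiTimeSeries) -> RoiTimeSeries:
    """Residualize each ROI channel on [intercept, WM, CSF] by OLS.

    A constant nuisance channel carries no signal and is dropped with a
    warning rather than making the design singular.
    """
    cols = []
    for c in ("WM", "CSF"):
        if c not in ts.frame.columns:
            continue
        if np.ptp(ts.frame[c].to_numpy()) == 0:
            warnings.warn(
                f"nuisance channel {c} is constant; dropped from regression",
                RuntimeWarning, stacklevel=2,
            )
        else:
            cols.append(c)
    n = ts.n_volumes
    C = np.column_stack(
        [np.ones(n)] + [ts.frame[c].to_numpy(dtype=float) for c in cols]
    )
    Q, _ = np.linalg.qr(C)
    out = ts.frame.copy()
    roi = ts.roi_names
    Y = ts.frame[roi].to_numpy(dtype=float)
    out[roi] = Y - Q @ (Q.T @ Y)
    return RoiTimeSeries(ts.subject, out, ts.design, ts.tr_seconds,
                         dict(ts.truth))


def extract_condition_series(
    ts: RoiTimeSeries, condition: str, shift_tr: int = 2,
    block_len: int = BLOCK_LEN,
) -> pd.DataFrame:
    """Concatenated, per-block mean-centered ROI series for one condition.

    Each block contributes the ``block_len`` volumes starting ``shift_tr``
    after block onset (the hemodynamic rise).  A shifted window running off
    the end of the run is an error, not a silent truncation.
    """
    if condition not in CONDITIONS:
        raise ConfigError(
            f"unknown condition {condition!r}; expected one of {CONDITIONS}"
        )
    starts = _blocks(ts.design, condition)
    if not starts:
        raise DesignError(f"design contains no {condition!r} blocks")
    roi = ts.roi_names
    Y = ts.frame[roi].to_numpy(dtype=float)
    pieces = []
    for s in starts:
        run_len = 0
        while (s + run_len < ts.n_volumes
               and ts.design[s + run_len] == condition):
            run_len += 1
        if run_len != block_len:
            raise DesignError(
                f"{condition!r} block at volume {s} has {run_len} volumes, "
                f"expected {block_len}"
            )
        lo, hi = s + shift_tr, s + shift_tr + block_len
        if hi > ts.n_volumes:
            raise DesignError(
                f"shifted window [{lo}, {hi}) for block at {s} runs past "
                f"the {ts.n_volumes}-volume run"
            )
        seg = Y[lo:hi]
        pieces.append(seg - seg.mean(axis=0, keepdims=True))
    return pd.DataFrame(np.vstack(pieces), columns=roi)


def condition_correlation_matrix(
    face_series: pd.DataFrame, control_series: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Pearson correlations between ROI pairs over the concatenated series.

    By default the face-condition blocks are concatenated with the control
    blocks (112 volumes for the standard design); pass ``None`` for a
    face-only matrix.
    """
    if control_series is not None:
        if list(face_series.columns) != list(control_series.columns):
            raise ConfigError("face and control series have different ROIs")
        data = np.vstack([face_series.to_numpy(), control_series.to_numpy()])
    else:
        data = face_series.to_numpy()
    corr = np.corrcoef(data, rowvar=False)
    corr = (corr + corr.T) / 2.0
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=face_series.columns,
                        columns=face_series.columns)


def threshold_and_degree(
    corr: pd.DataFrame, r_min: float = 0.3
) -> tuple[np.ndarray, pd.Series]:
    """Adjacency (strict r > r_min, negatives never edges) and nodal degree."""
    C = corr.to_numpy() if isinstance(corr, pd.DataFrame) else np.asarray(corr)
    adj = C > r_min
    np.fill_diagonal(adj, False)
    adj = adj & adj.T
    names = (corr.columns if isinstance(corr, pd.DataFrame)
             else pd.RangeIndex(C.shape[0]))
    degree = pd.Series(adj.sum(axis=1), index=names, name="degree")
    return adj, degree


def connectivity_graph(
    ts: RoiTimeSeries, condition: str, r_min: float = 0.3,
    include_control: bool = True, shift_tr: int = 2,
) -> ConnectivityGraph:
    """Full chain: extract series, correlate, threshold, count degree."""
    face = extract_condition_series(ts, condition, shift_tr=shift_tr)
    control = (extract_condition_series(ts, "control", shift_tr=shift_tr)
               if include_control and condition != "control" else None)
    corr = condition_correlation_matrix(face, control)
    adj, degree = threshold_and_degree(corr, r_min=r_min)
    return ConnectivityGraph(condition, corr, adj, degree)


def percent_bsc(
    ts: RoiTimeSeries, condition: str, shift_tr: int = 2,
    block_len: int = BLOCK_LEN,
) -> pd.Series:
    """Percent BOLD signal change of a condition versus control, per ROI.

    100 * (mean shifted condition signal - mean shifted control signal)
    divided by the whole-run mean signal of the ROI.
    """
    roi = ts.roi_names
    Y = ts.frame[roi].to_numpy(dtype=float)

    def shifted_mean(cond):
        starts = _blocks(ts.design, cond)
        if not starts:
            raise DesignError(f"design contains no {cond!r} blocks")
        rows = []
        for s in starts:
            lo, hi = s + shift_tr, s + shift_tr + block_len
            if hi > ts.n_volumes:
                raise DesignError("shifted window runs past the run")
            rows.append(Y[lo:hi])
        return np.vstack(rows).mean(axis=0)

    run_mean = Y.mean(axis=0)
    if np.any(run_mean == 0):
        raise ConfigError("whole-run mean signal is zero for some ROI")
    bsc = 100.0 * (shifted_mean(condition) - shifted_mean("control")) / run_mean
    return pd.Series(bsc, index=roi, name=f"bsc_{condition}")


def standardize_phenotypes(
    table: pd.DataFrame, site_col: str = "site",
    id_cols: tuple[str, ...] = ("fid", "iid", "site", "sex"),
) -> pd.DataFrame:
    """Z-score every phenotype column within acquisition site.

    Non-phenotype identifier/covariate columns are passed through; after
    the transform each phenotype column has mean 0 and SD 1 per site.
    """
    out = table.copy()
    pheno_cols = [c for c in table.columns if c not in id_cols]
    grouped = out.groupby(site_col, observed=True)[pheno_cols]
    out[pheno_cols] = grouped.transform(
        lambda s: (s - s.mean()) / s.std(ddof=1)
    )
    return out


def degree_population_stats(
    graphs_per_subject: list[ConnectivityGraph],
) -> pd.DataFrame:
    """Per-ROI mean and population SD (ddof=0) of nodal degree across subjects."""
    if not graphs_per_subject:
        raise ConfigError("no graphs supplied")
    deg = pd.DataFrame([g.degree for g in graphs_per_subject])
    return pd.DataFrame(
        {"degree_mean": deg.mean(axis=0), "degree_sd": deg.std(axis=0, ddof=0)}
    )


def connection_proportions(
    graphs_per_subject: list[ConnectivityGraph],
) -> pd.DataFrame:
    """Fraction of subjects carrying each edge; diagonal fixed at 1."""
    if not graphs_per_subject:
        raise ConfigError("no graphs supplied")
    stack = np.stack([g.adjacency for g in graphs_per_subject]).astype(float)
    prop = stack.mean(axis=0)
    np.fill_diagonal(prop, 1.0)
    names = graphs_per_subject[0].corr.columns
    return pd.DataFrame(prop, index=names, columns=names)
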