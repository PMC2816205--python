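"""Multi-strain time-course expression datasets.

The central container is :class:`ExpressionDataset`: a gene x strain x
timepoint x replicate array of normalized (log-scale, RMA-style) expression
values, with one strain designated as the *prediction strain* and a boolean
per-(gene, strain) mask marking cells whose values are held out.  Masked
values stay in memory (masking changes visibility, not data) but every
accessor that feeds a predictor raises :class:`MaskedDataError` when asked
for them, so no model can accidentally read the answer.

On-disk format is a plain TSV with a one-line header: first column ``gene``,
remaining columns named ``<strain>.t<minutes>.r<replicate>`` (the ``.r<k>``
suffix may be omitted when there is a single replicate).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionDataset",
    "TargetSet",
    "PredictionMatrix",
    "MaskedDataError",
    "ExpressionTableError",
    "load_expression_table",
    "write_expression_table",
    "collapse_replicates",
    "mask_targets",
    "write_predictions",
    "read_predictions",
    "read_target_list",
    "write_target_list",
]


class MaskedDataError(RuntimeError):
    """Raised when code tries to read a held-out (masked) expression value."""


class ExpressionTableError(ValueError):
    """Raised for malformed expression tables; names the offending row/column."""


_COLUMN_RE = re.compile(r"^(?P<strain>.+)\.t(?P<time>[0-9]+(?:\.[0-9]+)?)(?:\.r(?P<rep>[0-9]+))?$")


def _format_time(t: float) -> str:
    return f"{t:g}"


@dataclass(frozen=True)
class TargetSet:
    """The genes to predict and the strain in which they are hidden."""

    genes: tuple[str, ...]
    prediction_strain: str

    def __post_init__(self) -> None:
        if len(self.genes) == 0:
            raise ValueError("TargetSet must contain at least one gene")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("TargetSet contains duplicate gene identifiers")

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in set(self.genes)


class ExpressionDataset:
    """Validated gene x strain x timepoint x replicate expression values.

    Parameters
    ----------
    genes
        Unique gene identifiers, in dataset order (the order used for all
        deterministic tie-breaks downstream).
    strains
        Strain labels; ``prediction_strain`` must be one of them.
    prediction_strain
        The strain in which target expression is hidden and predicted.
    timepoints
        Strictly increasing measurement times in minutes.
    values
        Array of shape (n_genes, n_strains, n_timepoints, n_replicates).
    mask
        Boolean (n_genes, n_strains); True marks held-out cells.  Masked
        entries may occur only in the prediction strain.
    """

    def __init__(
        self,
        genes: Sequence[str],
        strains: Sequence[str],
        prediction_strain: str,
        timepoints: Sequence[float],
        values: np.ndarray,
        mask: np.ndarray | None = None,
    ) -> None:
        self.genes = tuple(str(g) for g in genes)
        self.strains = tuple(str(s) for s in strains)
        self.prediction_strain = str(prediction_strain)
        self.timepoints = tuple(float(t) for t in timepoints)
        values = np.asarray(values, dtype=float)
        if values.ndim == 3:
            values = values[..., np.newaxis]
        self._values = values
        if mask is None:
            mask = np.zeros((len(self.genes), len(self.strains)), dtype=bool)
        self.mask = np.asarray(mask, dtype=bool)
        self._gene_index = {g: i for i, g in enumerate(self.genes)}
        self._strain_index = {s: i for i, s in enumerate(self.strains)}
        self._validate()

    # -- validation ---------------------------------------------------

    def _validate(self) -> None:
        if len(self._gene_index) != len(self.genes):
            dupes = sorted({g for g in self.genes if self.genes.count(g) > 1})
            raise ExpressionTableError(f"duplicate gene identifiers: {dupes}")
        if self.prediction_strain not in self._strain_index:
            raise ValueError(
                f"prediction strain {self.prediction_strain!r} not among strains {self.strains}"
            )
        tp = np.asarray(self.timepoints)
        if tp.size < 1 or np.any(np.diff(tp) <= 0):
            raise ValueError("timepoints must be non-empty and strictly increasing")
        expected = (len(self.genes), len(self.strains), len(self.timepoints))
        if self._values.shape[:3] != expected or self._values.ndim != 4:
            raise ValueError(
                f"values shape {self._values.shape} incompatible with "
                f"{expected} genes/strains/timepoints"
            )
        if self.mask.shape != (len(self.genes), len(self.strains)):
            raise ValueError("mask must be (n_genes, n_strains)")
        pred = self._strain_index[self.prediction_strain]
        other = np.delete(np.arange(len(self.strains)), pred)
        if self.mask[:, other].any():
            raise ValueError("masked entries are only allowed in the prediction strain")
        visible = ~self.mask[:, :, np.newaxis, np.newaxis]
        if not np.all(np.isfinite(self._values) | ~np.broadcast_to(visible, self._values.shape)):
            bad = np.argwhere(~np.isfinite(self._values) & np.broadcast_to(visible, self._values.shape))
            g, s = bad[0][:2]
            raise ExpressionTableError(
                f"non-finite value for gene {self.genes[g]!r}, strain {self.strains[s]!r}"
            )

    # -- basic properties ---------------------------------------------

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_strains(self) -> int:
        return len(self.strains)

    @property
    def n_timepoints(self) -> int:
        return len(self.timepoints)

    @property
    def n_replicates(self) -> int:
        return self._values.shape[3]

    @property
    def complete_strains(self) -> tuple[str, ...]:
        """Strains with no held-out data (everything except the prediction strain)."""
        return tuple(s for s in self.strains if s != self.prediction_strain)

    def gene_index(self, gene: str) -> int:
        try:
            return self._gene_index[gene]
        except KeyError:
            raise KeyError(f"unknown gene identifier {gene!r}") from None

    def strain_index(self, strain: str) -> int:
        try:
            return self._strain_index[strain]
        except KeyError:
            raise KeyError(f"unknown strain label {strain!r}") from None

    def is_masked(self, gene: str, strain: str) -> bool:
        return bool(self.mask[self.gene_index(gene), self.strain_index(strain)])

    @property
    def masked_genes(self) -> tuple[str, ...]:
        pred = self._strain_index[self.prediction_strain]
        return tuple(g for g, m in zip(self.genes, self.mask[:, pred]) if m)

    @property
    def unmasked_genes(self) -> tuple[str, ...]:
        pred = self._strain_index[self.prediction_strain]
        return tuple(g for g, m in zip(self.genes, self.mask[:, pred]) if not m)

    # -- accessors (mask-aware) ---------------------------------------

    def profile(self, gene: str, strain: str, replicates: str = "mean") -> np.ndarray:
        """Expression profile of one gene in one strain.

        ``replicates="mean"`` returns the per-timepoint replicate average
        (length n_timepoints); ``"concat"`` returns replicates appended as
        extra coordinates (length n_timepoints * n_replicates).
        """
        gi, si = self.gene_index(gene), self.strain_index(strain)
        if self.mask[gi, si]:
            raise MaskedDataError(f"gene {gene!r} is masked in strain {strain!r}")
        block = self._values[gi, si]  # (T, R)
        if replicates == "mean":
            return block.mean(axis=1)
        if replicates == "concat":
            return block.T.ravel()  # r1 timecourse, then r2, ...
        raise ValueError(f"unknown replicate handling {replicates!r}")

    def strain_matrix(
        self, strain: str, genes: Sequence[str] | None = None, replicates: str = "mean"
    ) -> np.ndarray:
        """Gene x timepoint matrix for one strain; refuses masked genes."""
        si = self.strain_index(strain)
        idx = (
            np.arange(self.n_genes)
            if genes is None
            else np.array([self.gene_index(g) for g in genes])
        )
        masked = idx[self.mask[idx, si]]
        if masked.size:
            raise MaskedDataError(
                f"genes {[self.genes[i] for i in masked[:5]]} are masked in strain {strain!r}"
            )
        block = self._values[idx, si]  # (n, T, R)
        if replicates == "mean":
            return block.mean(axis=2)
        if replicates == "concat":
            return block.transpose(0, 2, 1).reshape(len(idx), -1)
        raise ValueError(f"unknown replicate handling {replicates!r}")

    def complete_profiles(self, replicates: str = "mean") -> np.ndarray:
        """Per-gene concatenation of all complete-strain profiles.

        Shape (n_genes, n_complete_strains * n_timepoints[* n_replicates]);
        this is the space in which the combined gene-gene distance lives.
        """
        parts = [self.strain_matrix(s, replicates=replicates) for s in self.complete_strains]
        return np.concatenate(parts, axis=1)

    # -- transformations ----------------------------------------------

    def copy(self) -> "ExpressionDataset":
        return ExpressionDataset(
            self.genes,
            self.strains,
            self.prediction_strain,
            self.timepoints,
            self._values.copy(),
            self.mask.copy(),
        )

    def collapse_replicates(self, method: str = "mean") -> "ExpressionDataset":
        """Average replicates per (gene, strain, timepoint); idempotent."""
        if method != "mean":
            raise ValueError(f"unsupported replicate collapse method {method!r}")
        collapsed = self._values.mean(axis=3, keepdims=True)
        return ExpressionDataset(
            self.genes,
            self.strains,
            self.prediction_strain,
            self.timepoints,
            collapsed,
            self.mask.copy(),
        )

    def mask_targets(self, targets: TargetSet) -> "ExpressionDataset":
        """Return a copy with the target genes masked in the prediction strain."""
        if targets.prediction_strain != self.prediction_strain:
            raise ValueError(
                f"target set is for strain {targets.prediction_strain!r}, "
                f"dataset predicts {self.prediction_strain!r}"
            )
        mask = self.mask.copy()
        pred = self._strain_index[self.prediction_strain]
        for g in targets.genes:
            mask[self.gene_index(g), pred] = True
        return ExpressionDataset(
            self.genes,
            self.strains,
            self.prediction_strain,
            self.timepoints,
            self._values.copy(),
            mask,
        )

    def equals(self, other: "ExpressionDataset") -> bool:
        return (
            self.genes == other.genes
            and self.strains == other.strains
            and self.prediction_strain == other.prediction_strain
            and self.timepoints == other.timepoints
            and np.array_equal(self._values, other._values)
            and np.array_equal(self.mask, other.mask)
        )


def collapse_replicates(ds: ExpressionDataset, method: str = "mean") -> ExpressionDataset:
    return ds.collapse_replicates(method=method)


def mask_targets(ds: ExpressionDataset, targets: TargetSet) -> ExpressionDataset:
    return ds.mask_targets(targets)


@dataclass
class PredictionMatrix:
    """Predicted target-gene x timepoint values for the prediction strain."""

    genes: tuple[str, ...]
    timepoints: tuple[float, ...]
    values: np.ndarray
    model: str = "unknown"
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.genes = tuple(self.genes)
        self.timepoints = tuple(float(t) for t in self.timepoints)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.genes) == 0:
            raise ValueError("empty prediction matrix")
        if self.values.shape != (len(self.genes), len(self.timepoints)):
            raise ValueError(
                f"prediction values shape {self.values.shape} != "
                f"({len(self.genes)}, {len(self.timepoints)})"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("prediction matrix contains non-finite values")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.genes), columns=list(self.timepoints))


# ---------------------------------------------------------------------------
# I/O


def _parse_columns(columns: Iterable[str]) -> list[tuple[str, float, int]]:
    parsed = []
    for col in columns:
        m = _COLUMN_RE.match(col)
        if m is None:
            raise ExpressionTableError(
                f"column {col!r} does not follow the '<strain>.t<minutes>[.r<rep>]' convention"
            )
        rep = int(m.group("rep")) if m.group("rep") else 1
        parsed.append((m.group("strain"), float(m.group("time")), rep))
    return parsed


def load_expression_table(
    path, prediction_strain: str, layout: str = "dotted"
) -> ExpressionDataset:
    """Read a TSV expression table into an :class:`ExpressionDataset`.

    The only supported ``layout`` is ``"dotted"``: header columns named
    ``<strain>.t<minutes>.r<replicate>``.  Non-numeric cells and duplicate
    gene identifiers raise :class:`ExpressionTableError` naming the location.
    """
    if layout != "dotted":
        raise ValueError(f"unknown layout {layout!r}")
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ExpressionTableError("expression table needs a gene column plus data columns")
    gene_col = df.columns[0]
    genes = df[gene_col].tolist()
    dupes = sorted({g for g in genes if genes.count(g) > 1})
    if dupes:
        raise ExpressionTableError(f"duplicate gene identifiers: {dupes}")

    parsed = _parse_columns(df.columns[1:])
    strains = list(dict.fromkeys(s for s, _, _ in parsed))
    timepoints = sorted({t for _, t, _ in parsed})
    reps = sorted({r for _, _, r in parsed})
    n_rep = max(reps)
    if reps != list(range(1, n_rep + 1)):
        raise ExpressionTableError(f"replicate labels {reps} are not 1..{n_rep}")
    expected = {(s, t, r) for s in strains for t in timepoints for r in range(1, n_rep + 1)}
    if set(parsed) != expected:
        missing = sorted(expected - set(parsed))[:5]
        raise ExpressionTableError(f"incomplete strain/time/replicate grid; missing {missing}")

    values = np.empty((len(genes), len(strains), len(timepoints), n_rep))
    s_idx = {s: i for i, s in enumerate(strains)}
    t_idx = {t: i for i, t in enumerate(timepoints)}
    for col, (s, t, r) in zip(df.columns[1:], parsed):
        # python float() is correctly rounded; pandas' fast parser is not
        cells = df[col].tolist()
        parsed_vals = np.empty(len(cells))
        for row_i, cell in enumerate(cells):
            if cell is None or (isinstance(cell, float) and np.isnan(cell)):
                raise ExpressionTableError(
                    f"missing value in column {col!r}, gene row {genes[row_i]!r}"
                )
            try:
                parsed_vals[row_i] = float(cell)
            except ValueError:
                raise ExpressionTableError(
                    f"non-numeric value in column {col!r}, gene row {genes[row_i]!r}"
                ) from None
        values[:, s_idx[s], t_idx[t], r - 1] = parsed_vals

    return ExpressionDataset(genes, strains, prediction_strain, timepoints, values)


def write_expression_table(ds: ExpressionDataset, path) -> None:
    """Write the TSV form read back by :func:`load_expression_table`.

    Refuses datasets with masked cells: the on-disk table has no mask
    channel, so writing one would silently leak or lose held-out values.
    """
    if ds.mask.any():
        raise ValueError("cannot write a dataset with masked cells to a plain table")
    cols = {}
    for si, s in enumerate(ds.strains):
        for ti, t in enumerate(ds.timepoints):
            for r in range(ds.n_replicates):
                cols[f"{s}.t{_format_time(t)}.r{r + 1}"] = ds._values[:, si, ti, r]
    df = pd.DataFrame(cols, index=list(ds.genes))
    df.index.name = "gene"
    df.to_csv(path, sep="\t", float_format="%.17g")


def write_predictions(pred: PredictionMatrix, path) -> None:
    """Write a prediction matrix as TSV (gene rows, timepoint-in-minutes columns)."""
    df = pred.to_frame()
    df.columns = [f"t{_format_time(t)}" for t in pred.timepoints]
    df.index.name = "gene"
    df.to_csv(path, sep="\t", float_format="%.17g")


def read_predictions(path, model: str = "unknown") -> PredictionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    try:
        timepoints = [float(c.lstrip("t")) for c in df.columns]
    except ValueError:
        raise ExpressionTableError(f"malformed timepoint header in {path}") from None
    return PredictionMatrix(tuple(df.index), tuple(timepoints), df.to_numpy(), model=model)


def read_target_list(path, prediction_strain: str) -> TargetSet:
    with open(path) as fh:
        genes = [line.strip() for line in fh if line.strip()]
    return TargetSet(tuple(genes), prediction_strain)


def write_target_list(targets: TargetSet, path) -> None:
    with open(path, "w") as fh:
        for g in targets.genes:
            fh.write(g + "\n")
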