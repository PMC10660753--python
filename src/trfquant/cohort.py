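"""Multi-dataset cohort matrices and abundance ratios.

Assembles fragments x datasets RPM matrices with the display conventions
used for cross-tissue tRF comparison: sub-threshold cells shown as 0 RPM,
columns grouped by bioproject, rows keyed by (sequence, source tRNA label,
length, structural class), optionally interleaving rows from two source
tRNAs by length so isodecoder/isoacceptor pairs can be read side by side.
Display copies cap values at a linear color scale maximum (default
1000 RPM); the raw matrix is always exported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .classifier import SelectedFragment
from .fragment_index import FragmentIndex
from .profiler import Profile

__all__ = [
    "DatasetMeta",
    "RowKey",
    "CohortMatrix",
    "read_metadata",
    "assemble_matrix",
    "abundance_ratio",
    "export_matrix",
    "read_matrix",
]

UNDEFINED = None  # abundance_ratio's "undefined" value


@dataclass(frozen=True)
class DatasetMeta:
    dataset_id: str
    bioproject: str
    tissue: str
    disease: str = ""
    cell_line: str | None = None
    treatment: str | None = None

    def __post_init__(self) -> None:
        if not self.tissue:
            raise ValueError(f"dataset {self.dataset_id}: tissue must be non-empty")


class RowKey(NamedTuple):
    sequence: str
    source: str
    length: int
    label: str


@dataclass(frozen=True)
class CohortMatrix:
    """Fragments x datasets RPM matrix with sub-threshold cells set to 0."""

    row_keys: tuple[RowKey, ...]
    columns: tuple[tuple[str, str], ...]  # (bioproject, dataset_id)
    values: np.ndarray  # shape (n_rows, n_cols)
    threshold_rpm: float
    cap_for_display: float = 1000.0

    def to_frame(self) -> pd.DataFrame:
        idx = pd.MultiIndex.from_tuples(
            self.row_keys, names=["sequence", "source", "length", "class"]
        )
        cols = pd.MultiIndex.from_tuples(
            self.columns, names=["bioproject", "dataset_id"]
        )
        return pd.DataFrame(self.values, index=idx, columns=cols)

    @property
    def dataset_ids(self) -> tuple[str, ...]:
        return tuple(d for _, d in self.columns)


def read_metadata(path: str | Path) -> list[DatasetMeta]:
    """Read the dataset metadata TSV (dataset_id, bioproject, tissue, ...)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    metas = []
    for row in df.itertuples(index=False):
        metas.append(
            DatasetMeta(
                dataset_id=row.dataset_id,
                bioproject=row.bioproject,
                tissue=row.tissue,
                disease=getattr(row, "disease", ""),
                cell_line=getattr(row, "cell_line", "") or None,
                treatment=getattr(row, "treatment", "") or None,
            )
        )
    return metas


def assemble_matrix(
    profiles: Sequence[Profile],
    metas: Iterable[DatasetMeta],
    selections: Mapping[str, Sequence[SelectedFragment]],
    interleave: bool = False,
    cap_for_display: float = 1000.0,
) -> CohortMatrix:
    """Assemble the cohort matrix from per-dataset profiles and selections.

    ``selections`` maps dataset_id to the vicinity-selected fragments of that
    dataset's profile.  The row set is the union across datasets; a cell is
    the fragment's RPM when it passes the threshold in that dataset and 0
    otherwise.  With ``interleave`` rows sort by (length, source) so two
    source tRNAs alternate line by line; the default sort is (source, length).
    """
    meta_by_id: dict[str, DatasetMeta] = {}
    for m in metas:
        if m.dataset_id in meta_by_id:
            raise ValueError(f"duplicate dataset_id {m.dataset_id!r} in metadata")
        meta_by_id[m.dataset_id] = m

    seen: set[str] = set()
    thresholds: set[float] = set()
    for p in profiles:
        if p.dataset_id in seen:
            raise ValueError(f"duplicate dataset_id {p.dataset_id!r} among profiles")
        seen.add(p.dataset_id)
        if p.dataset_id not in meta_by_id:
            raise ValueError(f"profile {p.dataset_id!r} missing from metadata")
        if p.threshold_rpm is None:
            raise ValueError(
                f"profile {p.dataset_id!r} has no threshold applied"
            )
        thresholds.add(p.threshold_rpm)
    threshold = max(thresholds) if thresholds else 0.0

    # union of selected row keys; cells from the thresholded profiles
    cells: dict[tuple[RowKey, str], float] = {}
    keys: set[RowKey] = set()
    for p in profiles:
        for sel in selections.get(p.dataset_id, ()):
            row = sel.row
            if row.passes_threshold is False:
                continue
            key = RowKey(row.sequence, sel.source_label, row.length, sel.label.value)
            keys.add(key)
            cells[(key, p.dataset_id)] = row.rpm

    if interleave:
        row_keys = tuple(sorted(keys, key=lambda k: (k.length, k.source, k.sequence)))
    else:
        row_keys = tuple(sorted(keys, key=lambda k: (k.source, k.length, k.sequence)))

    columns = tuple(
        sorted(
            ((meta_by_id[p.dataset_id].bioproject, p.dataset_id) for p in profiles),
        )
    )
    values = np.zeros((len(row_keys), len(columns)))
    for i, key in enumerate(row_keys):
        for j, (_, did) in enumerate(columns):
            values[i, j] = cells.get((key, did), 0.0)

    return CohortMatrix(
        row_keys=row_keys,
        columns=columns,
        values=values,
        threshold_rpm=threshold,
        cap_for_display=cap_for_display,
    )


def abundance_ratio(
    profile: Profile,
    frag_a: str,
    frag_b: str,
    index: FragmentIndex | None = None,
) -> float | None:
    """Ratio rpm(a)/rpm(b) when both pass the threshold, else ``None``.

    A sequence absent from the fragment index is a hard error (it can never
    have an abundance); a sequence absent from the profile rows simply has
    0 RPM and yields an undefined ratio.
    """
    if index is not None:
        for seq in (frag_a, frag_b):
            if index.lookup(seq) is None:
                raise KeyError(f"sequence {seq!r} is not in the fragment index")
    if profile.threshold_rpm is None:
        raise ValueError("profile has no threshold applied")
    row_a = profile.row_for(frag_a)
    row_b = profile.row_for(frag_b)
    if index is None and (row_a is None or row_b is None):
        missing = frag_a if row_a is None else frag_b
        raise KeyError(f"sequence {missing!r} not found in profile (no index given)")
    if row_a is None or not row_a.passes_threshold:
        return UNDEFINED
    if row_b is None or not row_b.passes_threshold:
        return UNDEFINED
    return row_a.rpm / row_b.rpm


def export_matrix(
    matrix: CohortMatrix,
    path_prefix: str | Path,
    display_cap: float | None = None,
) -> tuple[Path, Path]:
    """Write the raw RPM matrix and the display (capped) matrix as a TSV pair.

    Header row 1 carries dataset ids, header row 2 bioprojects.  Returns
    (raw_path, display_path).
    """
    cap = matrix.cap_for_display if display_cap is None else display_cap
    prefix = Path(path_prefix)
    raw_path = prefix.with_name(prefix.name + ".raw.tsv")
    disp_path = prefix.with_name(prefix.name + ".display.tsv")

    def _write(path: Path, values: np.ndarray) -> None:
        with open(path, "w") as fh:
            ids = "\t".join(d for _, d in matrix.columns)
            projects = "\t".join(b for b, _ in matrix.columns)
            fh.write(f"sequence\tsource\tlength\tclass\t{ids}\n")
            fh.write(f"#\t\t\t\t{projects}\n")
            for key, row in zip(matrix.row_keys, values):
                cells = "\t".join(f"{v:.4f}" for v in row)
                fh.write(f"{key.sequence}\t{key.source}\t{key.length}\t{key.label}\t{cells}\n")

    _write(raw_path, matrix.values)
    _write(disp_path, np.minimum(matrix.values, cap))
    return raw_path, disp_path


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read back an exported matrix TSV (raw or display) as a DataFrame."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        projects = fh.readline().rstrip("\n").split("\t")[4:]
        rows = []
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            rows.append(parts)
    dataset_ids = header[4:]
    idx = pd.MultiIndex.from_tuples(
        [(r[0], r[1], int(r[2]), r[3]) for r in rows],
        names=["sequence", "source", "length", "class"],
    )
    cols = pd.MultiIndex.from_tuples(
        list(zip(projects, dataset_ids)), names=["bioproject", "dataset_id"]
    )
    values = np.array([[float(v) for v in r[4:]] for r in rows]) if rows else np.empty((0, len(dataset_ids)))
    return pd.DataFrame(values, index=idx, columns=cols)


def plot_heatmap(matrix: CohortMatrix, path: str | Path) -> None:
    """Convenience heatmap export (linear color scale up to the display cap)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = matrix.to_frame()
    fig, ax = plt.subplots(
        figsize=(max(4, 0.4 * len(matrix.columns)), max(3, 0.3 * len(matrix.row_keys)))
    )
    im = ax.imshow(
        np.minimum(matrix.values, matrix.cap_for_display),
        aspect="auto",
        cmap="viridis",
        vmin=0,
        vmax=matrix.cap_for_display,
    )
    ax.set_xticks(range(len(matrix.columns)))
    ax.set_xticklabels([d for _, d in matrix.columns], rotation=90, fontsize=6)
    ax.set_yticks(range(len(matrix.row_keys)))
    ax.set_yticklabels(
        [f"{k.source} {k.length}nt {k.label}" for k in matrix.row_keys], fontsize=6
    )
    fig.colorbar(im, ax=ax, label="RPM (capped)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
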