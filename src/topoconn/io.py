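"""File formats, the ROI table, and run configuration.

All matrices travel as delimited text: power matrices as trials x ROIs
with a header row of ROI labels; distance and single-linkage matrices as
square tables with ROI labels on both the header row and the first
column.  Barcodes are two-column TSV (epsilon, n_components); dendrograms
export to Newick via :meth:`topoconn.filtration.Dendrogram.to_newick`.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .filtration import Barcode, SingleLinkageMatrix
from .network import DistanceMatrix, PowerMatrix

__all__ = [
    "RoiTable",
    "default_roi_table",
    "RunConfig",
    "read_power_matrix",
    "write_power_matrix",
    "read_distance_matrix",
    "write_distance_matrix",
    "write_slm",
    "read_slm",
    "write_barcode",
    "read_barcode",
]


# ---------------------------------------------------------------------------
# ROI table
#
# SYNTHETIC RECONSTRUCTION: a 76-parcel cortical node table (38 regions per
# hemisphere from the AAL anatomical parcellation, excluding subcortical and
# cerebellar structures), with resting-state-network tags (DMN, VN, SMN, AN,
# DAN) assigned from standard network groupings.  It is a plausible stand-in
# for study-specific supplementary node lists, not a copy of any one of them.

# (abbreviation, full name, network) — one row per region, both hemispheres.
_AAL_CORTICAL: list[tuple[str, str, str]] = [
    ("PRE", "precentral gyrus", "SMN"),
    ("F1", "superior frontal gyrus, dorsolateral", "other"),
    ("F1O", "superior frontal gyrus, orbital part", "other"),
    ("F2", "middle frontal gyrus", "DAN"),
    ("F2O", "middle frontal gyrus, orbital part", "other"),
    ("F3OP", "inferior frontal gyrus, opercular part", "other"),
    ("F3T", "inferior frontal gyrus, triangular part", "other"),
    ("F3O", "inferior frontal gyrus, orbital part", "other"),
    ("RO", "rolandic operculum", "AN"),
    ("SMA", "supplementary motor area", "SMN"),
    ("OC", "olfactory cortex", "other"),
    ("F1M", "superior frontal gyrus, medial", "DMN"),
    ("F1MO", "superior frontal gyrus, medial orbital", "DMN"),
    ("GR", "gyrus rectus", "other"),
    ("IN", "insula", "other"),
    ("ACIN", "anterior cingulate gyrus", "DMN"),
    ("MCIN", "median cingulate gyrus", "other"),
    ("PCIN", "posterior cingulate gyrus", "DMN"),
    ("V1", "calcarine fissure and surrounding cortex", "VN"),
    ("Q", "cuneus", "VN"),
    ("LING", "lingual gyrus", "VN"),
    ("O1", "superior occipital gyrus", "VN"),
    ("O2", "middle occipital gyrus", "VN"),
    ("O3", "inferior occipital gyrus", "VN"),
    ("FUSI", "fusiform gyrus", "VN"),
    ("POST", "postcentral gyrus", "SMN"),
    ("P1", "superior parietal gyrus", "DAN"),
    ("P2", "inferior parietal gyrus", "DAN"),
    ("SMG", "supramarginal gyrus", "AN"),
    ("AG", "angular gyrus", "DMN"),
    ("PQ", "precuneus", "DMN"),
    ("PCL", "paracentral lobule", "SMN"),
    ("HES", "heschl gyrus", "AN"),
    ("T1", "superior temporal gyrus", "AN"),
    ("T1P", "temporal pole: superior temporal gyrus", "other"),
    ("T2", "middle temporal gyrus", "other"),
    ("T2P", "temporal pole: middle temporal gyrus", "other"),
    ("T3", "inferior temporal gyrus", "other"),
]


@dataclass(frozen=True)
class RoiTable:
    """Ordered node table: (index, abbreviation, full name, hemisphere, network)."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        required = {"abbreviation", "full_name", "hemisphere", "network"}
        missing = required - set(t.columns)
        if missing:
            raise ValueError(f"RoiTable missing columns: {sorted(missing)}")
        if t["abbreviation"].duplicated().any():
            raise ValueError("ROI abbreviations must be unique")
        if list(t.index) != list(range(len(t))):
            raise ValueError("RoiTable index must be contiguous from 0")

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(self.table["abbreviation"])

    def __len__(self) -> int:
        return len(self.table)

    def network(self, abbreviation: str) -> str:
        row = self.table[self.table["abbreviation"] == abbreviation]
        if row.empty:
            raise KeyError(abbreviation)
        return str(row["network"].iloc[0])


def default_roi_table() -> RoiTable:
    """The bundled 76-node cortical table (left then right hemisphere)."""
    rows = []
    for hemi, suffix in (("L", ".L"), ("R", ".R")):
        for abbr, name, net in _AAL_CORTICAL:
            rows.append(
                {
                    "abbreviation": abbr + suffix,
                    "full_name": name,
                    "hemisphere": hemi,
                    "network": net,
                }
            )
    return RoiTable(table=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# run configuration


@dataclass(frozen=True)
class RunConfig:
    """Everything one end-to-end run needs.

    ``input_manifest`` points at a cohort manifest written by
    :func:`topoconn.synthetic.write_cohort` (or hand-built in the same
    JSON layout); alternatively ``cohort_spec`` holds a CohortSpec-style
    mapping to simulate from.  Defaults mirror a 76-node resting-state
    analysis: slope window 11-66 components, 10,000 permutations, alphas
    0.05 (slope test), 0.001 (SLM map, uncorrected) and 0.05 family-wise
    for clinical correlations.
    """

    output_dir: str
    input_manifest: str | None = None
    cohort_spec: Mapping | None = None
    band: str = "theta"
    slope_window: tuple[int, int] = (11, 66)
    n_permutations: int = 10_000
    alpha_slope: float = 0.05
    alpha_slm: float = 0.001
    alpha_clinical: float = 0.05
    family_size: int | None = None
    clinical_covariates: tuple[str, ...] = ()
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        object.__setattr__(self, "slope_window", tuple(self.slope_window))
        object.__setattr__(
            self, "clinical_covariates", tuple(self.clinical_covariates)
        )
        self.validate()

    def validate(self) -> None:
        if (self.input_manifest is None) == (self.cohort_spec is None):
            raise ValueError(
                "exactly one of input_manifest and cohort_spec is required"
            )
        for name in ("alpha_slope", "alpha_slm", "alpha_clinical"):
            a = getattr(self, name)
            if not 0 < a < 1:
                raise ValueError(f"{name} must be in (0, 1), got {a}")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        low, high = self.slope_window
        if not low < high:
            raise ValueError("slope window low must be < high")
        if self.family_size is not None and self.family_size < 1:
            raise ValueError("family_size must be a positive integer")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Load from JSON or YAML (keys = field names)."""
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must hold a mapping")
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        """Short stable hash of the analysis settings, stamped onto outputs.

        Excludes ``output_dir`` and ``log_level``: two runs of the same
        analysis written to different places share a hash.
        """
        d = self.to_dict()
        d.pop("output_dir", None)
        d.pop("log_level", None)
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# delimited-text matrix I/O


def _parse_labels(cells: list[str], path: Path) -> tuple[str, ...]:
    labels = tuple(c.strip() for c in cells)
    seen: set[str] = set()
    for c, lab in enumerate(labels):
        if lab in seen:
            raise ValueError(
                f"{path}: duplicate ROI label {lab!r} in header (column {c + 1})"
            )
        seen.add(lab)
    return labels


def _read_body(
    lines: list[str], n_cols: int, path: Path, first_line: int, skip_first_col: bool
) -> np.ndarray:
    rows = []
    for r, line in enumerate(lines, start=first_line):
        cells = line.rstrip("\n").split("\t")
        if skip_first_col:
            cells = cells[1:]
        if len(cells) != n_cols:
            raise ValueError(
                f"{path}: line {r} has {len(cells)} columns, expected {n_cols}"
            )
        try:
            rows.append([float(c) for c in cells])
        except ValueError:
            for c, cell in enumerate(cells):
                try:
                    float(cell)
                except ValueError:
                    raise ValueError(
                        f"{path}: non-numeric cell {cell!r} at line {r}, "
                        f"column {c + 1}"
                    ) from None
            raise
    return np.array(rows)


def read_power_matrix(
    path: str | Path, subject_id: str | None = None, band: str = "theta"
) -> PowerMatrix:
    """Read a trials x ROIs power matrix (TSV, ROI-label header row)."""
    path = Path(path)
    lines = path.read_text().splitlines()
    if len(lines) < 2:
        raise ValueError(f"{path}: need a header row and at least one trial")
    labels = _parse_labels(lines[0].split("\t"), path)
    values = _read_body(lines[1:], len(labels), path, 2, skip_first_col=False)
    return PowerMatrix(
        subject_id=subject_id or path.stem,
        band=band,
        values=values,
        roi_labels=labels,
    )


def write_power_matrix(pm: PowerMatrix, path: str | Path) -> None:
    """Write a power matrix as TSV with full float precision (round-trips)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("\t".join(pm.roi_labels) + "\n")
        for row in pm.values:
            fh.write("\t".join(repr(float(v)) for v in row) + "\n")


def _write_square(values: np.ndarray, labels: tuple[str, ...], path: Path) -> None:
    with path.open("w") as fh:
        fh.write("\t" + "\t".join(labels) + "\n")
        for lab, row in zip(labels, values):
            fh.write(lab + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def _read_square(path: Path) -> tuple[np.ndarray, tuple[str, ...]]:
    lines = path.read_text().splitlines()
    if len(lines) < 2:
        raise ValueError(f"{path}: empty square matrix file")
    labels = _parse_labels(lines[0].split("\t")[1:], path)
    values = _read_body(lines[1:], len(labels), path, 2, skip_first_col=True)
    if values.shape[0] != len(labels):
        raise ValueError(
            f"{path}: {values.shape[0]} rows for {len(labels)} labels"
        )
    return values, labels


def write_distance_matrix(dm: DistanceMatrix, path: str | Path) -> None:
    _write_square(dm.values, dm.roi_labels, Path(path))


def read_distance_matrix(path: str | Path) -> DistanceMatrix:
    values, labels = _read_square(Path(path))
    return DistanceMatrix(values=values, roi_labels=labels)


def write_slm(slm: SingleLinkageMatrix, path: str | Path) -> None:
    _write_square(slm.values, slm.roi_labels, Path(path))


def read_slm(path: str | Path) -> SingleLinkageMatrix:
    values, labels = _read_square(Path(path))
    return SingleLinkageMatrix(values=values, roi_labels=labels)


def write_barcode(bc: Barcode, path: str | Path) -> None:
    """Two-column TSV: epsilon, n_components (one row per merge event)."""
    with Path(path).open("w") as fh:
        fh.write("epsilon\tn_components\n")
        for eps, n in bc.merge_events:
            fh.write(f"{eps!r}\t{n}\n")


def read_barcode(path: str | Path, n_nodes: int | None = None) -> Barcode:
    lines = Path(path).read_text().splitlines()
    if not lines or lines[0].split("\t") != ["epsilon", "n_components"]:
        raise ValueError(f"{path}: expected an epsilon/n_components header")
    events = tuple(
        (float(cells[0]), int(cells[1]))
        for cells in (line.split("\t") for line in lines[1:])
    )
    if n_nodes is None:
        n_nodes = int(events[0][1]) + 1 if events else 1
    return Barcode(n_nodes=n_nodes, merge_events=events)
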