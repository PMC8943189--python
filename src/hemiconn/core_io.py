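"""Containers and plain-text I/O for weighted structural connectomes.

A connectome is a symmetric, nonnegative, zero-diagonal weight matrix whose
rows/columns are bound to an ordered atlas node table.  Weights carry the
semantics of streamline counts between parcellated gray-matter regions.
Matrices are stored as dense, tab-separated text with a label header row and
column — small enough (79 x 79) to stay human-inspectable.

The hemispheric split produces, per subject, an ipsilesional and a
contralesional 40-node matrix (39 lateralized nodes plus the shared
brainstem); interhemispheric edges are dropped, and the contralesional
matrix is permuted by the left/right homolog map so that row *k* of both
matrices refers to homologous regions.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "NodeEntry",
    "NodeTable",
    "Connectome",
    "ClinicalRecord",
    "HemisphericPair",
    "read_connectome",
    "write_connectome",
    "read_clinical_table",
    "write_clinical_table",
    "split_hemispheres",
]

HEMISPHERES = ("left", "right", "midline")
TISSUE_CLASSES = ("cortical", "subcortical", "cerebellar", "brainstem")
SUBGROUPS = ("precentral", "postcentral", "insular", "frontal")

SYMMETRY_TOL = 1e-9


class ValidationError(ValueError):
    """Raised when an input violates a container invariant."""


@dataclass(frozen=True)
class NodeEntry:
    label: str
    hemisphere: str  # left | right | midline
    tissue_class: str  # cortical | subcortical | cerebellar | brainstem

    def __post_init__(self) -> None:
        if self.hemisphere not in HEMISPHERES:
            raise ValidationError(f"unknown hemisphere {self.hemisphere!r}")
        if self.tissue_class not in TISSUE_CLASSES:
            raise ValidationError(f"unknown tissue class {self.tissue_class!r}")


@dataclass(frozen=True)
class NodeTable:
    """Ordered atlas nodes; the order defines matrix row/column semantics."""

    entries: tuple[NodeEntry, ...]
    homolog_map: dict[str, str] = field(default_factory=dict)  # left label -> right label

    def __post_init__(self) -> None:
        labels = [e.label for e in self.entries]
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise ValidationError(f"duplicate node labels: {dupes}")
        lab = set(labels)
        left = {e.label for e in self.entries if e.hemisphere == "left"}
        right = {e.label for e in self.entries if e.hemisphere == "right"}
        for k, v in self.homolog_map.items():
            if k not in left or v not in right:
                raise ValidationError(
                    f"homolog pair {k!r}->{v!r} does not map a left label to a right label"
                )
            if k not in lab or v not in lab:
                raise ValidationError(f"homolog pair {k!r}->{v!r} not in table")
        if len(set(self.homolog_map.values())) != len(self.homolog_map):
            raise ValidationError("homolog_map is not injective")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def labels(self) -> list[str]:
        return [e.label for e in self.entries]

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(label) from None

    def hemisphere_labels(self, hemisphere: str) -> list[str]:
        return [e.label for e in self.entries if e.hemisphere == hemisphere]

    @property
    def midline_labels(self) -> list[str]:
        return self.hemisphere_labels("midline")

    def check_atlas_structure(self) -> None:
        """Require the whole-brain layout used for hemispheric splitting.

        Two lateralized node sets in homolog bijection plus exactly one
        midline (brainstem) node.
        """
        mid = self.midline_labels
        if len(mid) != 1:
            raise ValidationError(
                f"expected exactly one midline node, found {len(mid)}: {mid}"
            )
        left = self.hemisphere_labels("left")
        right = self.hemisphere_labels("right")
        if set(self.homolog_map) != set(left) or set(
            self.homolog_map.values()
        ) != set(right):
            raise ValidationError(
                "homolog_map is not a bijection between left and right labels"
            )


def _check_weights(weights: np.ndarray, n: int, tol: float = SYMMETRY_TOL) -> np.ndarray:
    w = np.asarray(weights, dtype=float)
    if w.shape != (n, n):
        raise ValidationError(f"weight matrix shape {w.shape} != ({n}, {n})")
    if not np.all(np.isfinite(w)):
        raise ValidationError("weights contain non-finite entries")
    if np.any(w < 0):
        i, j = np.unravel_index(np.argmin(w), w.shape)
        raise ValidationError(f"negative weight {w[i, j]} at ({i}, {j})")
    asym = np.abs(w - w.T)
    worst = np.unravel_index(np.argmax(asym), asym.shape)
    if asym[worst] > tol:
        raise ValidationError(
            f"matrix asymmetric: |w[{worst[0]},{worst[1]}] - w[{worst[1]},{worst[0]}]|"
            f" = {asym[worst]:g} exceeds tolerance {tol:g}"
        )
    w = (w + w.T) / 2.0  # symmetrize residual rounding noise
    if np.any(np.diag(w) != 0):
        raise ValidationError("diagonal must be zero (no self-connections)")
    return w


@dataclass
class Connectome:
    """Symmetric nonnegative weighted adjacency matrix bound to a NodeTable."""

    nodes: NodeTable
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.weights = _check_weights(self.weights, len(self.nodes))

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def to_frame(self) -> pd.DataFrame:
        labels = self.nodes.labels
        return pd.DataFrame(self.weights, index=labels, columns=labels)


def read_connectome(path, nodes: NodeTable | None = None) -> Connectome:
    """Read a dense labeled TSV connectome.

    The first row and first column carry node labels.  If ``nodes`` is given,
    the file's labels must match it exactly (same order); otherwise a
    NodeTable is inferred from the labels (see :func:`infer_node_table`).
    """
    frame = pd.read_csv(path, sep="\t", index_col=0)
    row_labels = [str(x) for x in frame.index]
    col_labels = [str(x) for x in frame.columns]
    if row_labels != col_labels:
        raise ValidationError(
            f"row/column label mismatch in {path}: {row_labels[:3]}... vs {col_labels[:3]}..."
        )
    if nodes is not None:
        if row_labels != nodes.labels:
            missing = sorted(set(nodes.labels) - set(row_labels))
            extra = sorted(set(row_labels) - set(nodes.labels))
            raise ValidationError(
                f"labels in {path} do not match the supplied node table"
                f" (missing={missing}, unexpected={extra})"
            )
        table = nodes
    else:
        table = infer_node_table(row_labels)
    return Connectome(table, frame.to_numpy(dtype=float))


def write_connectome(conn: Connectome, path) -> None:
    """Write a dense labeled TSV; round-trips through read_connectome to 1e-12."""
    conn.to_frame().to_csv(path, sep="\t", float_format="%.17g")


_LATERAL_RE = re.compile(r"^(lh|rh)-(.+)$")


def infer_node_table(labels: list[str]) -> NodeTable:
    """Build a NodeTable from ``lh-``/``rh-`` prefixed labels.

    Unprefixed labels are treated as midline/brainstem.  Tissue classes are
    not recoverable from a bare matrix file and default to cortical
    (cerebellum and brainstem recognized by name).
    """
    entries = []
    lefts: dict[str, str] = {}
    for lab in labels:
        m = _LATERAL_RE.match(lab)
        if m is None:
            entries.append(NodeEntry(lab, "midline", "brainstem"))
            continue
        side = "left" if m.group(1) == "lh" else "right"
        base = m.group(2)
        tissue = "cerebellar" if "cerebellum" in base else "cortical"
        entries.append(NodeEntry(lab, side, tissue))
        if side == "left":
            lefts[base] = lab
    homolog = {}
    for lab in labels:
        m = _LATERAL_RE.match(lab)
        if m and m.group(1) == "rh" and m.group(2) in lefts:
            homolog[lefts[m.group(2)]] = lab
    return NodeTable(tuple(entries), homolog)


# ---------------------------------------------------------------------------
# clinical records


@dataclass
class ClinicalRecord:
    subject_id: str
    lesion_side: str  # left | right
    subgroup: tuple[str, ...]  # subset of SUBGROUPS
    mrc: int  # 0..5 muscle strength
    nihss: int | None  # 0..42, may be missing
    who_grade: int  # 2..4
    tumor_volume_cm3: float
    rmt_pathological: float  # V/m
    rmt_healthy: float  # V/m

    def __post_init__(self) -> None:
        if self.lesion_side not in ("left", "right"):
            raise ValidationError(f"lesion_side must be left/right, got {self.lesion_side!r}")
        for g in self.subgroup:
            if g not in SUBGROUPS:
                raise ValidationError(f"unknown subgroup tag {g!r}")
        if not 0 <= self.mrc <= 5:
            raise ValidationError(f"MRC {self.mrc} outside [0, 5]")
        if self.nihss is not None and not 0 <= self.nihss <= 42:
            raise ValidationError(f"NIHSS {self.nihss} outside [0, 42]")
        if self.who_grade not in (2, 3, 4):
            raise ValidationError(f"WHO grade {self.who_grade} not in {{2, 3, 4}}")
        if self.tumor_volume_cm3 < 0:
            raise ValidationError("tumor volume must be >= 0")
        if self.rmt_pathological <= 0 or self.rmt_healthy <= 0:
            raise ValidationError("RMT values must be > 0")

    @property
    def rmt_ratio(self) -> float:
        """Pathological-over-healthy resting motor threshold ratio."""
        return self.rmt_pathological / self.rmt_healthy


CLINICAL_COLUMNS = [
    "subject_id",
    "lesion_side",
    "subgroup",
    "mrc",
    "nihss",
    "who_grade",
    "tumor_volume_cm3",
    "rmt_pathological",
    "rmt_healthy",
]


def read_clinical_table(path) -> list[ClinicalRecord]:
    """Read the cohort clinical CSV; missing NIHSS cells are permitted."""
    frame = pd.read_csv(path, dtype={"subject_id": str})
    missing = [c for c in CLINICAL_COLUMNS if c not in frame.columns]
    if missing:
        raise ValidationError(f"clinical table missing columns: {missing}")
    records = []
    for row_number, row in enumerate(frame.itertuples(index=False), start=2):
        nihss = getattr(row, "nihss")
        try:
            records.append(
                ClinicalRecord(
                    subject_id=str(row.subject_id),
                    lesion_side=str(row.lesion_side),
                    subgroup=tuple(
                        t for t in str(row.subgroup).split(";") if t and t != "nan"
                    ),
                    mrc=int(row.mrc),
                    nihss=None if pd.isna(nihss) else int(nihss),
                    who_grade=int(row.who_grade),
                    tumor_volume_cm3=float(row.tumor_volume_cm3),
                    rmt_pathological=float(row.rmt_pathological),
                    rmt_healthy=float(row.rmt_healthy),
                )
            )
        except ValidationError as err:
            raise ValidationError(f"row {row_number}: {err}") from err
    return records


def clinical_frame(records: list[ClinicalRecord]) -> pd.DataFrame:
    """Tabular view of clinical records, rmt_ratio included as derived column."""
    return pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in records],
            "lesion_side": [r.lesion_side for r in records],
            "subgroup": [";".join(r.subgroup) for r in records],
            "mrc": [r.mrc for r in records],
            "nihss": [np.nan if r.nihss is None else r.nihss for r in records],
            "who_grade": [r.who_grade for r in records],
            "tumor_volume_cm3": [r.tumor_volume_cm3 for r in records],
            "rmt_pathological": [r.rmt_pathological for r in records],
            "rmt_healthy": [r.rmt_healthy for r in records],
            "rmt_ratio": [r.rmt_ratio for r in records],
        }
    )


def write_clinical_table(records: list[ClinicalRecord], path) -> None:
    clinical_frame(records).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# hemispheric split


def strip_side(label: str) -> str:
    """Hemisphere-neutral region name (drops the lh-/rh- prefix)."""
    m = _LATERAL_RE.match(label)
    return m.group(2) if m else label


@dataclass
class HemisphericPair:
    """Aligned ipsilesional / contralesional 40-node connectomes.

    Row *k* of both matrices refers to homologous regions; the last row is
    the shared brainstem node in the default atlas.
    """

    ipsi: Connectome
    contra: Connectome
    lesion_side: str

    @property
    def region_labels(self) -> list[str]:
        """Hemisphere-neutral labels valid for both matrices (alignment key)."""
        return [strip_side(l) for l in self.ipsi.nodes.labels]

    def __post_init__(self) -> None:
        ipsi_regions = [strip_side(l) for l in self.ipsi.nodes.labels]
        contra_regions = [strip_side(l) for l in self.contra.nodes.labels]
        if ipsi_regions != contra_regions:
            raise ValidationError("ipsi/contra matrices are not homolog-aligned")


def _hemi_subtable(table: NodeTable, labels: list[str]) -> NodeTable:
    by_label = {e.label: e for e in table.entries}
    return NodeTable(tuple(by_label[l] for l in labels), {})


def split_hemispheres(conn: Connectome, lesion_side: str) -> HemisphericPair:
    """Split a whole-brain connectome into ipsi-/contralesional matrices.

    Each output keeps that hemisphere's lateralized nodes plus the brainstem;
    interhemispheric (left<->right) edges are excluded.  Brainstem edges are
    assigned to the hemisphere of their lateralized endpoint.  The
    contralesional node order is permuted through the homolog map so both
    outputs are region-aligned row by row.
    """
    if lesion_side not in ("left", "right"):
        raise ValidationError(f"lesion_side must be left/right, got {lesion_side!r}")
    table = conn.nodes
    table.check_atlas_structure()
    brainstem = table.midline_labels[0]
    left_labels = table.hemisphere_labels("left")
    homolog = table.homolog_map
    # order both hemispheres by the left-label order so alignment is shared
    if lesion_side == "left":
        ipsi_labels = left_labels + [brainstem]
        contra_labels = [homolog[l] for l in left_labels] + [brainstem]
    else:
        ipsi_labels = [homolog[l] for l in left_labels] + [brainstem]
        contra_labels = left_labels + [brainstem]

    def extract(labels: list[str]) -> Connectome:
        idx = np.array([table.index(l) for l in labels])
        sub = conn.weights[np.ix_(idx, idx)]
        return Connectome(_hemi_subtable(table, labels), sub.copy())

    return HemisphericPair(extract(ipsi_labels), extract(contra_labels), lesion_side)
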