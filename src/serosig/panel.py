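"""Domain containers for multiplex serum-marker panels and their delimited-text IO.

A panel is a subjects x markers matrix of serum concentrations (pg/ml) with a
binary study-arm label per subject (1 = ASD case, 0 = TD control).  Exact zeros
are meaningful: they encode below-detection readings and are counted by the
mostly-zero filter, so they are never treated as missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Accepted label spellings (case-insensitive) -> binary arm code.
LABEL_VOCABULARY = {"ASD": 1, "TD": 0}
_CODE_TO_LABEL = {1: "ASD", 0: "TD"}


class PanelFormatError(ValueError):
    """A panel file or in-memory panel violates the format contract.

    The message names the offending row/column where one exists.
    """


@dataclass
class SubjectMeta:
    """Per-subject covariates: gender and collection site, optional age."""

    subject_id: str
    gender: str
    source: str
    age_years: float | None = None


@dataclass
class MarkerPanel:
    """Subjects x markers concentration matrix with binary arm labels.

    Parameters
    ----------
    subject_ids : list of str
        Unique subject identifiers, one per matrix row.
    labels : ndarray of {0, 1}
        Study arm per subject (1 = ASD, 0 = TD).
    marker_ids : list of str
        Unique marker names, one per matrix column.
    values : ndarray, shape (n_subjects, n_markers)
        Concentrations in pg/ml; finite, >= 0; exact 0 means below detection.
    replicates : ndarray, shape (n_subjects, n_markers, R), optional
        Technical replicate tensor from which ``values`` was aggregated.
    """

    subject_ids: list[str]
    labels: np.ndarray
    marker_ids: list[str]
    values: np.ndarray
    replicates: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        diagnostics = validate_panel(self, check_classes=False)
        if diagnostics:
            raise PanelFormatError("; ".join(diagnostics))

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    def subset_rows(self, rows: np.ndarray) -> "MarkerPanel":
        """Panel restricted to the given row indices (replicates carried along)."""
        rows = np.asarray(rows)
        return MarkerPanel(
            subject_ids=[self.subject_ids[i] for i in rows],
            labels=self.labels[rows],
            marker_ids=list(self.marker_ids),
            values=self.values[rows],
            replicates=None if self.replicates is None else self.replicates[rows],
        )

    def to_frame(self) -> pd.DataFrame:
        """Tabular form: subject_id, label, then one column per marker."""
        frame = pd.DataFrame(self.values, columns=self.marker_ids)
        frame.insert(0, "label", [_CODE_TO_LABEL[int(l)] for l in self.labels])
        frame.insert(0, "subject_id", self.subject_ids)
        return frame


def validate_panel(panel: MarkerPanel, *, check_classes: bool = True) -> list[str]:
    """Check every MarkerPanel invariant; return one diagnostic string per violation.

    Unlike the constructor this never raises: it is meant for auditing panels
    assembled from external files.  ``check_classes`` additionally requires both
    study arms to be present (an analysis precondition, not a storage one).
    """
    diags: list[str] = []
    n_s, n_m = len(panel.subject_ids), len(panel.marker_ids)
    if len(set(panel.subject_ids)) != n_s:
        diags.append("duplicate subject ids")
    if len(set(panel.marker_ids)) != n_m:
        diags.append("duplicate marker ids")
    if panel.values.shape != (n_s, n_m):
        diags.append(
            f"values shape {panel.values.shape} does not match "
            f"{n_s} subjects x {n_m} markers"
        )
        return diags  # downstream checks assume consistent shape
    if panel.labels.shape != (n_s,):
        diags.append(f"labels length {panel.labels.shape} != {n_s} subjects")
        return diags
    if not np.all(np.isfinite(panel.values)):
        bad = np.argwhere(~np.isfinite(panel.values))[0]
        diags.append(
            f"non-finite concentration at subject {panel.subject_ids[bad[0]]}, "
            f"marker {panel.marker_ids[bad[1]]}"
        )
    elif np.any(panel.values < 0):
        bad = np.argwhere(panel.values < 0)[0]
        diags.append(
            f"negative concentration at subject {panel.subject_ids[bad[0]]}, "
            f"marker {panel.marker_ids[bad[1]]}"
        )
    if not np.isin(panel.labels, (0, 1)).all():
        diags.append("labels outside {0, 1} (1 = ASD, 0 = TD)")
    elif check_classes and len(np.unique(panel.labels)) < 2:
        diags.append("both study arms (ASD and TD) must be present")
    if panel.replicates is not None:
        rep = np.asarray(panel.replicates, dtype=float)
        if rep.ndim != 3 or rep.shape[:2] != (n_s, n_m):
            diags.append(
                f"replicate tensor shape {rep.shape} does not match panel"
            )
        elif not np.allclose(rep.mean(axis=2), panel.values, atol=1e-8, rtol=1e-8):
            diags.append(
                "values do not equal the replicate aggregate (mean over replicates)"
            )
    return diags


def _parse_label(raw: object, row: object) -> int:
    token = str(raw).strip().upper()
    if token not in LABEL_VOCABULARY:
        raise PanelFormatError(
            f"unknown label {raw!r} for subject {row!r}; expected one of "
            f"{sorted(LABEL_VOCABULARY)} (case-insensitive)"
        )
    return LABEL_VOCABULARY[token]


def read_panel(
    matrix_path,
    meta_path=None,
    *,
    sep: str = ",",
) -> MarkerPanel | tuple[MarkerPanel, list[SubjectMeta]]:
    """Read a delimited panel matrix (and optionally a covariate file).

    The matrix file must have a header row with ``subject_id``, ``label`` and
    one column per marker; labels use the {ASD, TD} vocabulary.  Returns the
    panel alone, or ``(panel, meta)`` when ``meta_path`` is given.
    """
    frame = pd.read_csv(matrix_path, sep=sep, dtype={0: str}, float_precision="round_trip")
    for required in ("subject_id", "label"):
        if required not in frame.columns:
            raise PanelFormatError(f"missing required column {required!r}")
    marker_cols = [c for c in frame.columns if c not in ("subject_id", "label")]
    if not marker_cols:
        raise PanelFormatError("no marker columns found")
    subject_ids = frame["subject_id"].astype(str).tolist()
    labels = np.array(
        [_parse_label(v, s) for v, s in zip(frame["label"], subject_ids)]
    )
    values = (
        frame[marker_cols]
        .apply(pd.to_numeric, errors="coerce")
        .to_numpy(dtype=float)
    )
    if np.isnan(values).any():
        r, c = np.argwhere(np.isnan(values))[0]
        raise PanelFormatError(
            f"non-numeric or missing concentration at subject {subject_ids[r]}, "
            f"marker {marker_cols[c]}"
        )
    if (values < 0).any():
        r, c = np.argwhere(values < 0)[0]
        raise PanelFormatError(
            f"negative concentration {values[r, c]} at subject {subject_ids[r]}, "
            f"marker {marker_cols[c]}"
        )
    panel = MarkerPanel(subject_ids, labels, marker_cols, values)
    if meta_path is None:
        return panel
    return panel, read_meta(meta_path, panel, sep=sep)


def read_meta(meta_path, panel: MarkerPanel, *, sep: str = ",") -> list[SubjectMeta]:
    """Read a covariate file (subject_id, gender, source[, age_years])."""
    frame = pd.read_csv(meta_path, sep=sep, dtype={"subject_id": str})
    known = set(panel.subject_ids)
    meta = []
    for _, row in frame.iterrows():
        sid = str(row["subject_id"])
        if sid not in known:
            raise PanelFormatError(f"covariate subject {sid!r} not in panel")
        age = float(row["age_years"]) if "age_years" in frame.columns else None
        meta.append(SubjectMeta(sid, str(row["gender"]), str(row["source"]), age))
    return meta


def write_panel(panel: MarkerPanel, path, *, sep: str = ",") -> None:
    """Write the panel as delimited text at full float precision (round-trip stable).

    True zeros are serialized as ``0.0``, never as blanks, because the
    mostly-zero filter counts them.
    """
    # %.17g guarantees binary round-trip for float64
    panel.to_frame().to_csv(path, sep=sep, index=False, float_format="%.17g")


def write_meta(meta: list[SubjectMeta], path, *, sep: str = ",") -> None:
    pd.DataFrame(
        {
            "subject_id": [m.subject_id for m in meta],
            "gender": [m.gender for m in meta],
            "source": [m.source for m in meta],
            "age_years": [m.age_years for m in meta],
        }
    ).to_csv(path, sep=sep, index=False)
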