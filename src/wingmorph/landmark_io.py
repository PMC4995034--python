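"""Reading and writing TPS-dialect landmark files and specimen classifier tables.

The TPS format (as written by the TpsDig family of digitizing tools) stores one
record per specimen: an ``LM=<n>`` line, ``n`` whitespace-separated ``x y``
coordinate lines, followed by key lines such as ``ID=``, ``IMAGE=`` and
``SCALE=``.  Keys are accepted case-insensitively and in any order after the
coordinate block; unknown keys are ignored with a logged note, since TPS files
in the wild vary.  ``SCALE`` is applied multiplicatively to the coordinates on
read, so all in-memory coordinates share one (arbitrary but consistent) unit.

Coordinates are taken exactly as stored: no image-origin y-flip is applied.
Generalized Procrustes results are invariant to a reflection convention applied
uniformly across a dataset digitized by a single operator.

Landmark indices are 1-based in every user-facing interface and 0-based
internally.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: label fields carried by every specimen (site may be empty)
LABEL_FIELDS = ("genus", "subgenus", "species", "site")

#: TPS keys we understand (case-insensitive)
_KNOWN_KEYS = {"LM", "ID", "IMAGE", "SCALE"}


class TpsParseError(ValueError):
    """Malformed TPS file; carries the 1-based line number of the offence."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


@dataclass
class LandmarkConfiguration:
    """One specimen's labelled 2-D landmark configuration.

    Parameters
    ----------
    specimen_id : str
        Unique specimen identifier.
    coords : (k, 2) ndarray
        Landmark coordinates in image units (scale already applied).
    scale : float, optional
        Units-per-pixel factor that was applied on read, if any.
    labels : dict
        Taxonomic labels: genus, subgenus, species, and optionally site.
    """

    specimen_id: str
    coords: np.ndarray
    scale: float | None = None
    labels: dict = field(default_factory=dict)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError(
                f"specimen {self.specimen_id!r}: coords must be (k, 2), "
                f"got {self.coords.shape}"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"specimen {self.specimen_id!r}: non-finite coordinate")
        if self.scale is not None and self.scale <= 0:
            raise ValueError(f"specimen {self.specimen_id!r}: SCALE must be positive")
        # degenerate configurations (exactly coincident landmarks) are rejected
        k = self.coords.shape[0]
        if len(np.unique(self.coords, axis=0)) < k:
            raise ValueError(
                f"specimen {self.specimen_id!r}: coincident landmarks "
                "(degenerate configuration)"
            )

    @property
    def landmark_count(self) -> int:
        return self.coords.shape[0]


@dataclass
class ShapeDataset:
    """An ordered collection of landmark configurations sharing one landmark count."""

    configurations: list[LandmarkConfiguration]

    def __post_init__(self):
        if not self.configurations:
            raise ValueError("empty dataset")
        counts = {c.landmark_count for c in self.configurations}
        if len(counts) != 1:
            raise ValueError(f"inconsistent landmark counts: {sorted(counts)}")
        ids = [c.specimen_id for c in self.configurations]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate specimen ids: {dupes}")

    def __len__(self) -> int:
        return len(self.configurations)

    def __iter__(self):
        return iter(self.configurations)

    @property
    def landmark_count(self) -> int:
        return self.configurations[0].landmark_count

    @property
    def specimen_ids(self) -> list[str]:
        return [c.specimen_id for c in self.configurations]

    def coords_array(self) -> np.ndarray:
        """Stack all configurations into an (n, k, 2) array."""
        return np.stack([c.coords for c in self.configurations])

    def labels_frame(self) -> pd.DataFrame:
        """Per-specimen label table indexed like the dataset (one row per specimen)."""
        rows = [
            {"specimen_id": c.specimen_id,
             **{f: c.labels.get(f, "") for f in LABEL_FIELDS}}
            for c in self.configurations
        ]
        return pd.DataFrame(rows)

    def group_labels(self, level: str) -> np.ndarray:
        """Per-specimen group label at ``level`` (genus/subgenus/species/site)."""
        if level not in LABEL_FIELDS:
            raise ValueError(f"unknown grouping level {level!r}")
        out = np.array([c.labels.get(level, "") for c in self.configurations])
        if (out == "").any():
            missing = [c.specimen_id for c, lab in zip(self.configurations, out)
                       if lab == ""]
            raise ValueError(
                f"{len(missing)} specimens lack a {level!r} label "
                f"(e.g. {missing[:3]}); supply a classifier table"
            )
        return out

    def subset(self, mask: Sequence[bool]) -> "ShapeDataset":
        """Dataset restricted to the specimens where ``mask`` is True."""
        kept = [c for c, m in zip(self.configurations, mask) if m]
        return ShapeDataset(kept)

    def to_long_frame(self) -> pd.DataFrame:
        """Tidy long-format table: one row per (specimen, landmark)."""
        rows = []
        for c in self.configurations:
            for i, (x, y) in enumerate(c.coords, start=1):
                rows.append({"specimen_id": c.specimen_id, "landmark": i,
                             "x": x, "y": y,
                             **{f: c.labels.get(f, "") for f in LABEL_FIELDS}})
        return pd.DataFrame(rows)


def read_classifier(path: str | Path) -> pd.DataFrame:
    """Read a specimen classifier table (delimited text with a header).

    Required columns: specimen_id, genus, subgenus, species; ``site`` optional.
    """
    table = pd.read_csv(path, sep=None, engine="python", dtype=str).fillna("")
    required = {"specimen_id", "genus", "subgenus", "species"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"classifier table {path}: missing columns {sorted(missing)}")
    if "site" not in table.columns:
        table["site"] = ""
    if table["specimen_id"].duplicated().any():
        raise ValueError(f"classifier table {path}: duplicate specimen ids")
    return table


def read_tps(path: str | Path, classifier: str | Path | None = None) -> ShapeDataset:
    """Parse a TPS landmark file into a :class:`ShapeDataset`.

    Parameters
    ----------
    path : path
        TPS file; every record must begin with ``LM=<n>`` with identical ``n``.
    classifier : path, optional
        Classifier table joined on specimen id.  Records without a classifier
        row get empty labels and a logged warning.
    """
    path = Path(path)
    lines = path.read_text().splitlines()

    records: list[dict] = []
    current: dict | None = None
    n_coords_expected = 0

    def _finish(lineno: int):
        if current is None:
            return
        if len(current["coords"]) != n_coords_expected:
            raise TpsParseError(
                f"record {current.get('id') or len(records) + 1!r}: expected "
                f"{n_coords_expected} coordinate lines, got {len(current['coords'])}",
                lineno,
            )
        records.append(current)

    for lineno, raw in enumerate(lines, start=1):
        text = raw.strip()
        if not text:
            continue
        if "=" in text and not _looks_numeric(text):
            key, _, value = text.partition("=")
            key = key.strip().upper()
            value = value.strip()
            if key == "LM":
                _finish(lineno)
                try:
                    n = int(value)
                except ValueError:
                    raise TpsParseError(f"malformed LM count {value!r}", lineno)
                if n < 1:
                    raise TpsParseError(f"malformed LM count {n}", lineno)
                if records and n != n_coords_expected:
                    raise TpsParseError(
                        f"inconsistent landmark count: LM={n} after LM={n_coords_expected}",
                        lineno,
                    )
                n_coords_expected = n
                current = {"coords": [], "id": None, "scale": None, "lm_line": lineno}
            elif current is None:
                raise TpsParseError(f"{key}= before any LM= record", lineno)
            elif key == "ID":
                current["id"] = value
            elif key == "SCALE":
                try:
                    current["scale"] = float(value)
                except ValueError:
                    raise TpsParseError(f"malformed SCALE {value!r}", lineno)
            elif key == "IMAGE":
                current["image"] = value
            else:
                logger.info("%s:%d: ignoring unknown TPS key %s=", path, lineno, key)
        else:
            if current is None:
                raise TpsParseError("coordinate line before any LM= record", lineno)
            fields = text.split()
            if len(fields) != 2:
                raise TpsParseError(
                    f"coordinate line with {len(fields)} fields (expected 2)", lineno
                )
            try:
                xy = (float(fields[0]), float(fields[1]))
            except ValueError:
                raise TpsParseError(f"non-numeric coordinate {text!r}", lineno)
            if len(current["coords"]) >= n_coords_expected:
                raise TpsParseError(
                    f"more than LM={n_coords_expected} coordinate lines in record",
                    lineno,
                )
            current["coords"].append(xy)
    _finish(len(lines))

    if not records:
        raise TpsParseError(f"{path}: no LM= records found")

    label_map: dict[str, dict] = {}
    if classifier is not None:
        table = read_classifier(classifier)
        for _, row in table.iterrows():
            label_map[row["specimen_id"]] = {f: row[f] for f in LABEL_FIELDS}

    configs = []
    for i, rec in enumerate(records):
        sid = rec["id"] if rec["id"] else f"record_{i + 1}"
        coords = np.array(rec["coords"], dtype=float)
        if rec["scale"] is not None:
            coords = coords * rec["scale"]
        labels = label_map.get(sid, {})
        if classifier is not None and sid not in label_map:
            logger.warning("specimen %r has no classifier row; labels left empty", sid)
        try:
            configs.append(
                LandmarkConfiguration(sid, coords, scale=rec["scale"], labels=dict(labels))
            )
        except ValueError as exc:
            raise TpsParseError(str(exc), rec["lm_line"]) from exc
    try:
        return ShapeDataset(configs)
    except ValueError as exc:
        raise TpsParseError(str(exc)) from exc


def _looks_numeric(text: str) -> bool:
    # a coordinate line never contains '='; keep the check future-proof anyway
    fields = text.split()
    if not fields:
        return False
    try:
        float(fields[0])
        return True
    except ValueError:
        return False


def write_tps(dataset: ShapeDataset, path: str | Path) -> None:
    """Write ``dataset`` as a TPS file.

    Coordinates are written at full precision with SCALE already applied, so
    ``read_tps(write_tps(d))`` reproduces coordinates exactly and in order.
    """
    if len(dataset) == 0:  # ShapeDataset forbids this, but guard the contract
        raise ValueError("cannot write an empty dataset")
    k = dataset.landmark_count
    out = []
    for c in dataset:
        out.append(f"LM={k}")
        for x, y in c.coords:
            out.append(f"{x:.17g} {y:.17g}")
        out.append(f"ID={c.specimen_id}")
    Path(path).write_text("\n".join(out) + "\n")


def write_classifier(dataset: ShapeDataset, path: str | Path) -> None:
    """Write the dataset's labels as a classifier CSV."""
    dataset.labels_frame().to_csv(path, index=False)


def select_landmarks(dataset: ShapeDataset, indices: Iterable[int]) -> ShapeDataset:
    """Restrict every configuration to the chosen landmarks (1-based indices).

    The order of ``indices`` is preserved; labels and specimen ids carry over.
    """
    idx = list(indices)
    if len(set(idx)) != len(idx):
        raise ValueError(f"duplicate landmark indices in {idx}")
    k = dataset.landmark_count
    for i in idx:
        if not (1 <= i <= k):
            raise ValueError(f"landmark index {i} out of range 1..{k}")
    sel = np.array(idx, dtype=int) - 1
    configs = [
        LandmarkConfiguration(
            c.specimen_id, c.coords[sel], scale=c.scale, labels=dict(c.labels)
        )
        for c in dataset
    ]
    return ShapeDataset(configs)
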