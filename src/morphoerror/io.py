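"""Reading, writing, validating and subsetting 3D landmark datasets.

The canonical on-disk representation is a long-format CSV with one row per
(individual, operator, replicate, landmark): columns ``individual_id,
operator_id, sex, replicate_id, landmark, x, y, z``.  A Morphologika-style
plain-text reader/writer is provided for interchange with classical
morphometrics software.  Coordinates are always millimetres; axes follow the
MRI convention X = right-left, Y = posterior-anterior, Z = superior-inferior.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

SEX_VALUES = ("F", "M", "unknown")

CSV_COLUMNS = [
    "individual_id",
    "operator_id",
    "sex",
    "replicate_id",
    "landmark",
    "x",
    "y",
    "z",
]


class LandmarkError(ValueError):
    """Raised on malformed or inconsistent landmark data."""


@dataclass(frozen=True)
class LandmarkPanel:
    """An ordered set of named landmarks with tissue/side tags and named subsets.

    The default facial panel has 15 landmarks: 10 on bone (including glabella,
    which is not among the five nasal soft-tissue points) and 5 nasal
    soft-tissue ones, carried as the named subsets ``all``, ``bone``, ``nose``.
    """

    names: tuple[str, ...]
    tissue: tuple[str, ...]
    side: tuple[str, ...]
    subsets: dict[str, tuple[int, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        p = len(self.names)
        if len(set(self.names)) != p:
            raise LandmarkError("duplicated landmark label in panel")
        if len(self.tissue) != p or len(self.side) != p:
            raise LandmarkError("tissue/side tags must match panel length")
        for t in self.tissue:
            if t not in ("bone", "soft"):
                raise LandmarkError(f"unknown tissue tag {t!r}")
        for s in self.side:
            if s not in ("midline", "left", "right"):
                raise LandmarkError(f"unknown side tag {s!r}")
        for name, idx in self.subsets.items():
            if any(i < 0 or i >= p for i in idx):
                raise LandmarkError(f"subset {name!r} has out-of-range indices")
        # every bilateral landmark needs its contralateral partner
        for i, s in enumerate(self.side):
            if s in ("left", "right"):
                partner = self._partner_name(self.names[i], s)
                if partner not in self.names:
                    raise LandmarkError(
                        f"bilateral landmark {self.names[i]!r} lacks partner"
                    )

    @staticmethod
    def _partner_name(name: str, side: str) -> str:
        a, b = (" left", " right") if side == "left" else (" right", " left")
        return name.replace(a, b)

    @property
    def size(self) -> int:
        return len(self.names)

    def subset_indices(self, subset_name: str) -> tuple[int, ...]:
        try:
            return self.subsets[subset_name]
        except KeyError:
            raise LandmarkError(
                f"unknown subset {subset_name!r}; available: "
                f"{sorted(self.subsets)}"
            ) from None

    def subset_panel(self, subset_name: str) -> "LandmarkPanel":
        """A new panel restricted to one named subset (indices re-based)."""
        idx = self.subset_indices(subset_name)
        pos = {old: new for new, old in enumerate(idx)}
        new_subsets = {}
        for name, sub in self.subsets.items():
            kept = tuple(pos[i] for i in sub if i in pos)
            if kept:
                new_subsets[name] = kept
        new_subsets["all"] = tuple(range(len(idx)))
        return LandmarkPanel(
            names=tuple(self.names[i] for i in idx),
            tissue=tuple(self.tissue[i] for i in idx),
            side=tuple(self.side[i] for i in idx),
            subsets=new_subsets,
        )

    def restrict_to(self, names: Sequence[str]) -> "LandmarkPanel":
        """Panel restricted to the given labels, kept in panel order."""
        missing = [n for n in names if n not in self.names]
        if missing:
            raise LandmarkError(f"labels not on panel: {missing}")
        idx = tuple(i for i, n in enumerate(self.names) if n in set(names))
        pos = {old: new for new, old in enumerate(idx)}
        subsets = {}
        for name, sub in self.subsets.items():
            kept = tuple(pos[i] for i in sub if i in pos)
            if kept:
                subsets[name] = kept
        subsets["all"] = tuple(range(len(idx)))
        return LandmarkPanel(
            names=tuple(self.names[i] for i in idx),
            tissue=tuple(self.tissue[i] for i in idx),
            side=tuple(self.side[i] for i in idx),
            subsets=subsets,
        )


def _default_panel() -> LandmarkPanel:
    # order follows the figure caption numbering of the facial configuration
    spec = [
        ("Glabella", "bone", "midline"),
        ("Soft nasion", "soft", "midline"),
        ("Hard nasion", "bone", "midline"),
        ("Pronasale", "soft", "midline"),
        ("Subnasale", "soft", "midline"),
        ("Anterior nasal spine", "bone", "midline"),
        ("Sella", "bone", "midline"),
        ("Alare left", "soft", "left"),
        ("Alare right", "soft", "right"),
        ("Orbitale left", "bone", "left"),
        ("Orbitale right", "bone", "right"),
        ("Porion left", "bone", "left"),
        ("Porion right", "bone", "right"),
        ("Zygion left", "bone", "left"),
        ("Zygion right", "bone", "right"),
    ]
    names = tuple(s[0] for s in spec)
    tissue = tuple(s[1] for s in spec)
    side = tuple(s[2] for s in spec)
    subsets = {
        "all": tuple(range(len(spec))),
        "bone": tuple(i for i, t in enumerate(tissue) if t == "bone"),
        "nose": tuple(i for i, t in enumerate(tissue) if t == "soft"),
    }
    return LandmarkPanel(names=names, tissue=tissue, side=side, subsets=subsets)


DEFAULT_PANEL = _default_panel()
assert DEFAULT_PANEL.size == 15
assert len(DEFAULT_PANEL.subsets["bone"]) == 10
assert len(DEFAULT_PANEL.subsets["nose"]) == 5


@dataclass(frozen=True)
class LandmarkConfiguration:
    """One digitization of all panel landmarks for one subject (mm)."""

    individual_id: str
    operator_id: str
    sex: str
    replicate_id: str
    coords: np.ndarray  # (p, 3)

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        object.__setattr__(self, "coords", coords)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise LandmarkError(
                f"coords must be (p, 3); got {coords.shape} for record "
                f"{self.key}"
            )
        if not np.all(np.isfinite(coords)):
            raise LandmarkError(f"non-finite coordinate in record {self.key}")
        if self.sex not in SEX_VALUES:
            raise LandmarkError(f"sex must be one of {SEX_VALUES}")

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.individual_id, self.operator_id, self.replicate_id)

    @property
    def label(self) -> str:
        return f"{self.individual_id}|{self.operator_id}"


@dataclass(frozen=True)
class LandmarkDataset:
    """A homogeneous collection of configurations sharing one panel."""

    panel: LandmarkPanel
    records: tuple[LandmarkConfiguration, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))
        keys = [r.key for r in self.records]
        if len(set(keys)) != len(keys):
            dup = next(k for k in keys if keys.count(k) > 1)
            raise LandmarkError(f"duplicated record key {dup}")
        for r in self.records:
            if r.coords.shape[0] != self.panel.size:
                raise LandmarkError(
                    f"record {r.key} has {r.coords.shape[0]} landmarks; "
                    f"panel defines {self.panel.size}"
                )

    def __len__(self) -> int:
        return len(self.records)

    def coords_array(self) -> np.ndarray:
        """All coordinates stacked as (n, p, 3)."""
        return np.stack([r.coords for r in self.records])

    def meta(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "individual_id": [r.individual_id for r in self.records],
                "operator_id": [r.operator_id for r in self.records],
                "sex": [r.sex for r in self.records],
                "replicate_id": [r.replicate_id for r in self.records],
            }
        )

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(r.label for r in self.records)

    def select_subset(self, subset_name: str) -> "LandmarkDataset":
        idx = list(self.panel.subset_indices(subset_name))
        panel = self.panel.subset_panel(subset_name)
        records = tuple(
            replace(r, coords=r.coords[idx]) for r in self.records
        )
        return LandmarkDataset(panel=panel, records=records)

    def filter(self, pred: Callable[[LandmarkConfiguration], bool]) -> "LandmarkDataset":
        return LandmarkDataset(
            panel=self.panel, records=tuple(r for r in self.records if pred(r))
        )


def select_subset(dataset: LandmarkDataset, subset_name: str) -> LandmarkDataset:
    """Restrict a dataset to a named landmark subset (metadata unchanged)."""
    return dataset.select_subset(subset_name)


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    return "morphologika" if path.suffix.lower() in (".txt", ".morph") else "csv"


def write_landmark_table(
    dataset: LandmarkDataset, path: str | Path, format: str | None = None
) -> None:
    """Write a dataset losslessly (floats via shortest exact repr)."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if len(dataset) == 0:
        raise LandmarkError("refusing to write an empty dataset")
    if fmt == "csv":
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(CSV_COLUMNS)
            for r in dataset.records:
                for name, xyz in zip(dataset.panel.names, r.coords):
                    w.writerow(
                        [
                            r.individual_id,
                            r.operator_id,
                            r.sex,
                            r.replicate_id,
                            name,
                            repr(float(xyz[0])),
                            repr(float(xyz[1])),
                            repr(float(xyz[2])),
                        ]
                    )
    elif fmt == "morphologika":
        lines = ["[individuals]", str(len(dataset)), "[landmarks]",
                 str(dataset.panel.size), "[dimensions]", "3", "[names]"]
        for r in dataset.records:
            lines.append(f"{r.individual_id}|{r.operator_id}|{r.sex}|{r.replicate_id}")
        lines.append("[rawpoints]")
        for r in dataset.records:
            lines.append(f"'{r.individual_id}|{r.operator_id}|{r.sex}|{r.replicate_id}")
            for xyz in r.coords:
                lines.append(" ".join(repr(float(v)) for v in xyz))
        path.write_text("\n".join(lines) + "\n")
    else:
        raise LandmarkError(f"unknown format {fmt!r}")


def _panel_for_labels(labels: Sequence[str], panel: LandmarkPanel | None) -> LandmarkPanel:
    if panel is not None:
        return panel.restrict_to(labels) if set(labels) != set(panel.names) else panel
    unknown = [l for l in labels if l not in DEFAULT_PANEL.names]
    if unknown:
        raise LandmarkError(
            f"labels not on the default panel: {unknown}; pass an explicit panel"
        )
    return DEFAULT_PANEL.restrict_to(labels)


def read_landmark_table(
    path: str | Path, format: str | None = None, panel: LandmarkPanel | None = None
) -> LandmarkDataset:
    """Read and validate a landmark table (long CSV or Morphologika text).

    Every record must carry exactly the panel's landmarks; a missing landmark
    is reported by record key and label.  Record order is preserved.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _infer_format(path, format)
    if fmt == "csv":
        return _read_csv(path, panel)
    if fmt == "morphologika":
        return _read_morphologika(path, panel)
    raise LandmarkError(f"unknown format {fmt!r}")


def _read_csv(path: Path, panel: LandmarkPanel | None) -> LandmarkDataset:
    df = pd.read_csv(
        path, dtype={c: str for c in CSV_COLUMNS[:5]}, float_precision="round_trip"
    )
    missing_cols = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing_cols:
        raise LandmarkError(f"CSV is missing columns {missing_cols}")
    for c in ("x", "y", "z"):
        vals = pd.to_numeric(df[c], errors="coerce")
        if vals.isna().any():
            i = int(vals.isna().idxmax())
            raise LandmarkError(
                f"non-numeric {c} at row {i} "
                f"(record {tuple(df.loc[i, CSV_COLUMNS[:2]])}, "
                f"landmark {df.loc[i, 'landmark']!r})"
            )
        df[c] = vals
    labels = list(dict.fromkeys(df["landmark"]))
    resolved = _panel_for_labels(labels, panel)
    order = {n: i for i, n in enumerate(resolved.names)}
    records = []
    key_cols = ["individual_id", "operator_id", "replicate_id"]
    for key, grp in df.groupby(key_cols, sort=False):
        got = set(grp["landmark"])
        missing = [n for n in resolved.names if n not in got]
        if missing:
            raise LandmarkError(f"record {key} is missing landmarks {missing}")
        if len(grp) != resolved.size:
            raise LandmarkError(
                f"record {key} has {len(grp)} landmark rows; expected {resolved.size}"
            )
        grp = grp.iloc[np.argsort([order[n] for n in grp["landmark"]])]
        sex = grp["sex"].iloc[0]
        records.append(
            LandmarkConfiguration(
                individual_id=key[0],
                operator_id=key[1],
                sex=sex if sex in SEX_VALUES else "unknown",
                replicate_id=key[2],
                coords=grp[["x", "y", "z"]].to_numpy(float),
            )
        )
    return LandmarkDataset(panel=resolved, records=tuple(records))


_KNOWN_BLOCKS = {"individuals", "landmarks", "dimensions", "names", "rawpoints"}


def _read_morphologika(path: Path, panel: LandmarkPanel | None) -> LandmarkDataset:
    blocks: dict[str, list[str]] = {}
    current: str | None = None
    for raw in path.read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("[") and line.endswith("]"):
            current = line[1:-1].lower()
            if current not in _KNOWN_BLOCKS:
                warnings.warn(f"ignoring unsupported Morphologika block [{current}]")
            blocks.setdefault(current, [])
            continue
        if current is not None:
            blocks[current].append(line)
    for req in ("individuals", "landmarks", "dimensions", "rawpoints"):
        if req not in blocks:
            raise LandmarkError(f"Morphologika file lacks [{req}] block")
    n = int(blocks["individuals"][0])
    p = int(blocks["landmarks"][0])
    dims = int(blocks["dimensions"][0])
    if dims != 3:
        raise LandmarkError(f"only 3D supported; file declares {dims} dimensions")
    if panel is None:
        if p == DEFAULT_PANEL.size:
            panel = DEFAULT_PANEL
        elif p == len(DEFAULT_PANEL.subsets["bone"]):
            panel = DEFAULT_PANEL.subset_panel("bone")
        elif p == len(DEFAULT_PANEL.subsets["nose"]):
            panel = DEFAULT_PANEL.subset_panel("nose")
        else:
            raise LandmarkError(
                f"cannot infer a panel for {p} landmarks; pass one explicitly"
            )
    if panel.size != p:
        raise LandmarkError(f"panel has {panel.size} landmarks; file declares {p}")
    records = []
    lines = blocks["rawpoints"]
    i = 0
    while i < len(lines):
        header = lines[i]
        if not header.startswith("'"):
            raise LandmarkError(f"expected a 'name line in [rawpoints]; got {header!r}")
        parts = header[1:].split("|")
        ind = parts[0]
        op = parts[1] if len(parts) > 1 else ""
        sex = parts[2] if len(parts) > 2 and parts[2] in SEX_VALUES else "unknown"
        rep = parts[3] if len(parts) > 3 else "r1"
        rows = lines[i + 1 : i + 1 + p]
        if len(rows) < p:
            raise LandmarkError(f"record {ind!r} has fewer than {p} coordinate lines")
        coords = np.array([[float(v) for v in row.split()] for row in rows])
        records.append(
            LandmarkConfiguration(
                individual_id=ind, operator_id=op, sex=sex, replicate_id=rep,
                coords=coords,
            )
        )
        i += 1 + p
    if len(records) != n:
        raise LandmarkError(
            f"[individuals] declares {n} but [rawpoints] holds {len(records)}"
        )
    return LandmarkDataset(panel=panel, records=tuple(records))
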