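"""Reading, writing and joining the study's on-disk formats.

Landmark configurations come in as TPS (``LM3`` blocks) or long-format
CSV; trees as Newick/NEXUS via :mod:`dendropy`; ecology tables as
CSV/TSV.  ``join_metadata`` assembles the validated study object and
reports (rather than errors on) species missing from one of the three
sources.
"""

from __future__ import annotations

import hashlib
import json
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .trees import TreeSet, read_trees  # noqa: F401  (re-exported)

HABITATS = ("reef", "shelf", "pelagic", "deep-sea")

__all__ = [
    "LandmarkScheme", "SpecimenTable", "EcologyRecord", "Study",
    "read_landmarks", "write_landmarks", "read_ecology", "write_ecology",
    "join_metadata", "RunManifest", "HABITATS",
]


class SchemaError(ValueError):
    """Input violates the declared landmark scheme."""


class ParseError(ValueError):
    """Malformed file content."""


# --------------------------------------------------------------------- #
# landmark scheme
# --------------------------------------------------------------------- #
@dataclass(frozen=True)
class LandmarkScheme:
    """Partition of the ``p`` landmarks into fixed points, sliding curve
    points and sliding surface points.

    ``curves`` are ordered open polylines given as landmark indices
    (0-based); their interior points slide along the curve tangent.
    Curve endpoints are anchors: they must be fixed landmarks (or shared
    curve junctions) and do not slide.
    """

    n_fixed: int
    curves: tuple = ()
    surface_ids: tuple = ()

    def __post_init__(self):
        object.__setattr__(self, "curves",
                           tuple(tuple(int(i) for i in c) for c in self.curves))
        object.__setattr__(self, "surface_ids",
                           tuple(int(i) for i in self.surface_ids))
        seen = {}
        for role, ids in (("fixed", range(self.n_fixed)),
                          ("surface", self.surface_ids)):
            for i in ids:
                if i in seen:
                    raise SchemaError(f"landmark {i} assigned to both "
                                      f"{seen[i]} and {role}")
                seen[i] = role
        for c in self.curves:
            if len(c) < 3:
                raise SchemaError("curves need >=3 points (interior slides)")
            for i in c[1:-1]:
                if i in seen:
                    raise SchemaError(f"landmark {i} assigned to both "
                                      f"{seen[i]} and curve-interior")
                seen[i] = "curve"

    @property
    def curve_interiors(self) -> np.ndarray:
        ids = [i for c in self.curves for i in c[1:-1]]
        return np.array(sorted(ids), dtype=int)

    @property
    def p(self) -> int:
        return (self.n_fixed + len(self.curve_interiors)
                + len(self.surface_ids))

    def roles(self) -> np.ndarray:
        """Array of ``'fixed' | 'curve' | 'surface'`` per landmark."""
        r = np.array(["fixed"] * self.p, dtype=object)
        r[self.curve_interiors] = "curve"
        r[list(self.surface_ids)] = "surface"
        return r


# --------------------------------------------------------------------- #
# specimens
# --------------------------------------------------------------------- #
@dataclass
class SpecimenTable:
    """Raw (device-unit) 3-D coordinates for each digitised specimen."""

    specimen_ids: list
    species_ids: list
    coords: np.ndarray            # (n_specimens, p, 3)
    scheme: LandmarkScheme
    provenance: str = ""

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise SchemaError("coords must be (n, p, 3)")
        if self.coords.shape[1] != self.scheme.p:
            raise SchemaError(
                f"coordinate landmark count {self.coords.shape[1]} does not "
                f"match scheme p={self.scheme.p}")
        if not np.all(np.isfinite(self.coords)):
            raise SchemaError("non-finite coordinates")
        if len(self.specimen_ids) != self.coords.shape[0]:
            raise SchemaError("specimen id / coordinate count mismatch")

    def __len__(self):
        return len(self.specimen_ids)

    @property
    def species(self) -> list:
        out, seen = [], set()
        for s in self.species_ids:
            if s not in seen:
                seen.add(s)
                out.append(s)
        return out


# --------------------------------------------------------------------- #
# ecology
# --------------------------------------------------------------------- #
@dataclass(frozen=True)
class EcologyRecord:
    species_id: str
    order: str
    habitat: str
    trophic_level: float
    diet: dict | None = None      # prey category -> proportion

    def __post_init__(self):
        if self.habitat not in HABITATS:
            raise SchemaError(
                f"habitat {self.habitat!r} not in {HABITATS} "
                f"(species {self.species_id})")
        if not (2.0 <= self.trophic_level <= 5.0):
            raise SchemaError(
                f"trophic level {self.trophic_level} outside [2, 5] "
                f"(species {self.species_id})")
        if self.diet is not None:
            vals = np.array(list(self.diet.values()), dtype=float)
            if np.any(vals < 0):
                raise SchemaError(f"negative diet proportion ({self.species_id})")
            if abs(vals.sum() - 1.0) > 1e-9:
                raise SchemaError(
                    f"diet proportions of {self.species_id} sum to "
                    f"{vals.sum():.6f}, not 1")


# --------------------------------------------------------------------- #
# readers / writers
# --------------------------------------------------------------------- #
_TPS_KEY = re.compile(r"^(LM3?|ID|IMAGE|SCALE)\s*=\s*(.*)$", re.I)


def _read_tps(path, scheme: LandmarkScheme) -> SpecimenTable:
    ids, coords = [], []
    cur, cur_id, expect = None, None, 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            m = _TPS_KEY.match(line)
            if m and m.group(1).upper().startswith("LM"):
                if cur is not None:
                    _close_tps_block(cur, cur_id, expect, ids, coords, lineno)
                expect = int(m.group(2))
                cur, cur_id = [], None
            elif m and m.group(1).upper() == "ID":
                cur_id = m.group(2).strip()
            elif m:
                continue   # IMAGE/SCALE ignored
            else:
                try:
                    xyz = [float(t) for t in line.split()]
                except ValueError:
                    raise ParseError(
                        f"{path}:{lineno}: non-numeric coordinate {line!r}")
                if len(xyz) != 3:
                    raise ParseError(
                        f"{path}:{lineno}: expected 3 coordinates, got {len(xyz)}")
                if cur is None:
                    raise ParseError(f"{path}:{lineno}: coordinates before LM3=")
                cur.append(xyz)
    if cur is not None:
        _close_tps_block(cur, cur_id, expect, ids, coords, "EOF")
    arr = np.array(coords, dtype=float)
    if arr.ndim != 3 or arr.shape[1] != scheme.p:
        got = arr.shape[1] if arr.ndim == 3 else "ragged"
        raise SchemaError(f"TPS landmark count {got} != scheme p={scheme.p}")
    return SpecimenTable(ids, [i.split("__")[0] for i in ids], arr, scheme,
                         provenance=str(path))


def _close_tps_block(cur, cur_id, expect, ids, coords, lineno):
    if len(cur) != expect:
        raise ParseError(
            f"TPS block {cur_id or len(ids)} declares LM3={expect} but has "
            f"{len(cur)} coordinate rows (at line {lineno})")
    ids.append(cur_id if cur_id is not None else f"spec_{len(ids)}")
    coords.append(cur)


def _read_csv_landmarks(path, scheme: LandmarkScheme) -> SpecimenTable:
    df = pd.read_csv(path, float_precision="round_trip")
    need = {"specimen", "landmark_index", "x", "y", "z"}
    if not need.issubset(df.columns):
        raise ParseError(f"landmark CSV needs columns {sorted(need)}")
    has_species = "species" in df.columns
    ids, spp, coords = [], [], []
    for spec_id, grp in df.groupby("specimen", sort=False):
        grp = grp.sort_values("landmark_index")
        if not np.array_equal(grp["landmark_index"].to_numpy(),
                              np.arange(scheme.p)):
            raise SchemaError(
                f"specimen {spec_id}: landmark indices must be 0..{scheme.p - 1}")
        ids.append(str(spec_id))
        spp.append(str(grp["species"].iloc[0]) if has_species
                   else str(spec_id).split("__")[0])
        coords.append(grp[["x", "y", "z"]].to_numpy(dtype=float))
    return SpecimenTable(ids, spp, np.array(coords), scheme,
                         provenance=str(path))


def read_landmarks(path, format: str, scheme: LandmarkScheme) -> SpecimenTable:
    """Read a specimen table; ``format`` is ``'tps'`` or ``'csv'``."""
    if format == "tps":
        return _read_tps(path, scheme)
    if format in ("csv", "pts"):
        return _read_csv_landmarks(path, scheme)
    raise ValueError(f"unknown landmark format {format!r}")


def write_landmarks(table: SpecimenTable, path, format: str = "csv") -> None:
    if format == "tps":
        with open(path, "w") as fh:
            for i, sid in enumerate(table.specimen_ids):
                fh.write(f"LM3={table.scheme.p}\n")
                for row in table.coords[i]:
                    fh.write(f"{row[0]:.17g} {row[1]:.17g} {row[2]:.17g}\n")
                fh.write(f"ID={sid}\n")
        return
    rows = []
    for i, sid in enumerate(table.specimen_ids):
        for j in range(table.scheme.p):
            x, y, z = table.coords[i, j]
            rows.append((sid, table.species_ids[i], j, x, y, z))
    pd.DataFrame(rows, columns=["specimen", "species", "landmark_index",
                                "x", "y", "z"]).to_csv(path, index=False,
                                                       float_format="%.17g")


def read_ecology(path) -> list:
    """Ecology CSV/TSV: species, order, habitat, trophic_level, then any
    number of ``diet_<category>`` proportion columns (optional)."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    diet_cols = [c for c in df.columns if c.startswith("diet_")]
    recs = []
    for _, row in df.iterrows():
        diet = None
        if diet_cols and not row[diet_cols].isna().any():
            raw = {c[5:]: float(row[c]) for c in diet_cols}
            tot = sum(raw.values())
            if tot > 0:
                diet = {k: v / tot for k, v in raw.items()}
        recs.append(EcologyRecord(str(row["species"]), str(row["order"]),
                                  str(row["habitat"]),
                                  float(row["trophic_level"]), diet))
    return recs


def write_ecology(records: list, path) -> None:
    cats = sorted({k for r in records if r.diet for k in r.diet})
    rows = []
    for r in records:
        row = {"species": r.species_id, "order": r.order,
               "habitat": r.habitat, "trophic_level": r.trophic_level}
        for c in cats:
            row[f"diet_{c}"] = r.diet.get(c, 0.0) if r.diet else np.nan
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# --------------------------------------------------------------------- #
# study object
# --------------------------------------------------------------------- #
@dataclass
class Study:
    """Validated join of specimens, ecology and trees."""

    specimens: SpecimenTable
    ecology: dict                       # species -> EcologyRecord
    trees: TreeSet | None
    missing: dict = field(default_factory=dict)

    @property
    def species(self) -> list:
        return self.specimens.species

    def ecology_frame(self) -> pd.DataFrame:
        rows = []
        for sp in self.species:
            r = self.ecology.get(sp)
            rows.append({"species": sp,
                         "order": r.order if r else None,
                         "habitat": r.habitat if r else None,
                         "trophic_level": r.trophic_level if r else np.nan})
        return pd.DataFrame(rows).set_index("species")

    def diet_matrix(self) -> pd.DataFrame:
        """Species x prey-category proportions, diet subset only."""
        rows, idx = [], []
        cats = sorted({k for r in self.ecology.values() if r.diet
                       for k in r.diet})
        for sp in self.species:
            r = self.ecology.get(sp)
            if r and r.diet:
                rows.append([r.diet.get(c, 0.0) for c in cats])
                idx.append(sp)
        return pd.DataFrame(rows, index=idx, columns=cats)

    def subset(self, which: str) -> "Study":
        """Named subsets: ``'has_diet'`` keeps species with diet rows."""
        if which != "has_diet":
            raise ValueError(f"unknown subset {which!r}")
        keep_sp = {sp for sp in self.species
                   if sp in self.ecology and self.ecology[sp].diet}
        keep = [i for i, sp in enumerate(self.specimens.species_ids)
                if sp in keep_sp]
        sub = SpecimenTable(
            [self.specimens.specimen_ids[i] for i in keep],
            [self.specimens.species_ids[i] for i in keep],
            self.specimens.coords[keep], self.specimens.scheme,
            provenance=self.specimens.provenance)
        return join_metadata(sub, list(self.ecology.values()), self.trees)


def join_metadata(specimens: SpecimenTable, ecology: list,
                  trees: TreeSet | None = None) -> Study:
    """Join specimens to ecology records and tree tips.

    Species present in one source but not another are reported in
    ``Study.missing``, not raised; duplicate ecology rows are an error.
    """
    by_sp = {}
    dups = []
    for r in sorted(ecology, key=lambda r: r.species_id):
        if r.species_id in by_sp:
            dups.append(r.species_id)
        by_sp[r.species_id] = r
    if dups:
        raise SchemaError(f"duplicate ecology entries: {sorted(set(dups))}")

    spp = set(specimens.species)
    missing = {
        "species_without_ecology": sorted(spp - set(by_sp)),
        "ecology_without_specimens": sorted(set(by_sp) - spp),
    }
    if trees is not None:
        tips = set(trees.tip_labels)
        missing["tree_tips_without_specimens"] = sorted(tips - spp)
        missing["species_not_in_tree"] = sorted(spp - tips)
    return Study(specimens, by_sp, trees, missing)


# --------------------------------------------------------------------- #
# run manifest
# --------------------------------------------------------------------- #
class RunManifest:
    """JSON log of seeds, parameters and input digests per pipeline stage."""

    def __init__(self):
        self.stages = []

    @staticmethod
    def digest(path) -> str:
        h = hashlib.sha256()
        with open(path, "rb") as fh:
            for chunk in iter(lambda: fh.read(65536), b""):
                h.update(chunk)
        return h.hexdigest()[:16]

    def log(self, stage: str, seed=None, params=None, inputs=None):
        self.stages.append({
            "stage": stage, "seed": seed, "params": params or {},
            "input_digests": {str(p): self.digest(p) for p in (inputs or [])},
        })

    def write(self, path):
        with open(path, "w") as fh:
            json.dump({"stages": self.stages}, fh, indent=2)
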