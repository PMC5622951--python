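"""Tabular I/O and validated containers for the probe-level pipeline.

Three dialects cover everything the pipeline exchanges on disk:

* probe-intensity matrices and the probe→transcript-cluster map as TSV,
* sample design tables (age group, sex, treatment, replicate pairing) as CSV,
* gene-set collections as GMT (tab-separated: id, description, members...).

Intensities are stored and exchanged on the *linear* fluorescence scale;
any log transform is internal to consumers.  Files are UTF-8, "." decimal,
no thousands separators, so that write→read round trips are bit-exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import numpy as np
import pandas as pd

AGE_GROUPS = ("adolescent_PND43", "adult_PND66")
SEXES = ("M", "F")
TREATMENTS = ("ethanol", "control")


class FormatError(ValueError):
    """A file does not conform to its declared dialect."""


class ValidationError(ValueError):
    """Data parse correctly but violate a container invariant."""


class DegenerateInputError(ValueError):
    """Input is structurally valid but numerically unusable (e.g. all-zero chip)."""


# ---------------------------------------------------------------------------
# ProbeMatrix
# ---------------------------------------------------------------------------

@dataclass
class ProbeMatrix:
    """Probe-level intensities (probes × samples) plus probe→cluster mapping.

    ``intensities`` is indexed by probe_id with one column per sample;
    ``cluster_map`` maps every probe_id to exactly one transcript-cluster id.
    Probe order within a cluster is preserved as given.
    """

    intensities: pd.DataFrame
    cluster_map: pd.Series

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        ix = self.intensities.index
        if ix.duplicated().any():
            dup = ix[ix.duplicated()][0]
            raise FormatError(f"duplicate probe_id {dup!r}")
        cols = self.intensities.columns
        if cols.duplicated().any():
            raise ValidationError("sample IDs are not unique")
        missing = ix.difference(self.cluster_map.index)
        if len(missing):
            raise FormatError(
                f"probe(s) without cluster mapping: {', '.join(map(repr, missing[:5]))}"
            )
        self.cluster_map = self.cluster_map.loc[ix]
        vals = self.intensities.to_numpy()
        if not np.isfinite(vals).all():
            bad = np.argwhere(~np.isfinite(vals))[0]
            raise ValidationError(
                f"non-finite intensity at probe {ix[bad[0]]!r}, sample {cols[bad[1]]!r}"
            )
        if (vals < 0).any():
            bad = np.argwhere(vals < 0)[0]
            raise ValidationError(
                f"negative intensity at probe {ix[bad[0]]!r}, sample {cols[bad[1]]!r}"
            )

    # -- convenience views --------------------------------------------------
    @property
    def probe_ids(self) -> pd.Index:
        return self.intensities.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.intensities.columns

    @property
    def cluster_ids(self) -> np.ndarray:
        return self.cluster_map.unique()

    def probes_per_cluster(self) -> pd.Series:
        return self.cluster_map.groupby(self.cluster_map, sort=False).size()


def read_probe_matrix(path: str | Path, map_path: str | Path) -> ProbeMatrix:
    """Read an intensity TSV and its probe→cluster map TSV into a ProbeMatrix."""
    intens = pd.read_csv(path, sep="\t", index_col="probe_id")
    cmap = pd.read_csv(map_path, sep="\t")
    for col in ("probe_id", "cluster_id"):
        if col not in cmap.columns:
            raise FormatError(f"map file missing column {col!r}")
    if cmap["probe_id"].duplicated().any():
        dup = cmap.loc[cmap["probe_id"].duplicated(), "probe_id"].iloc[0]
        raise FormatError(f"duplicate probe_id {dup!r} in map")
    cluster_map = cmap.set_index("probe_id")["cluster_id"].astype(str)
    return ProbeMatrix(intens, cluster_map)


def write_probe_matrix(pm: ProbeMatrix, path: str | Path, map_path: str | Path) -> None:
    pm.intensities.to_csv(path, sep="\t", index_label="probe_id")
    pm.cluster_map.rename("cluster_id").to_csv(map_path, sep="\t", index_label="probe_id")


# ---------------------------------------------------------------------------
# DesignTable
# ---------------------------------------------------------------------------

@dataclass
class DesignTable:
    """Sample factors: age group, sex, treatment, and optional treated↔control pairing.

    ``pair_id`` links exactly one ethanol-treated sample with one control sample of
    the same sex and age; pairs are the unit for which pairwise S-scores are formed.
    """

    table: pd.DataFrame

    REQUIRED = ("sample_id", "age_group", "sex", "treatment")

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        t = self.table
        for col in self.REQUIRED:
            if col not in t.columns:
                raise FormatError(f"design missing column {col!r}")
        if "pair_id" not in t.columns:
            t = t.assign(pair_id=pd.NA)
            self.table = t
        if t["sample_id"].duplicated().any():
            raise ValidationError("duplicate sample_id in design")
        for col, levels in (("age_group", AGE_GROUPS), ("sex", SEXES), ("treatment", TREATMENTS)):
            bad = set(t[col].unique()) - set(levels)
            if bad:
                raise ValidationError(f"unknown {col} level(s): {sorted(map(str, bad))}")
        paired = t[t["pair_id"].notna() & (t["pair_id"] != "")]
        for pid, grp in paired.groupby("pair_id"):
            if len(grp) != 2 or set(grp["treatment"]) != {"ethanol", "control"}:
                raise ValidationError(
                    f"pair_id {pid!r} must link exactly one treated and one control sample"
                )
            if grp["sex"].nunique() != 1 or grp["age_group"].nunique() != 1:
                raise ValidationError(f"pair_id {pid!r} links samples of different sex or age")

    def pairs(self, age_group: str | None = None) -> pd.DataFrame:
        """One row per pair_id: (pair_id, treated_id, control_id, sex, age_group)."""
        t = self.table
        paired = t[t["pair_id"].notna() & (t["pair_id"] != "")]
        if age_group is not None:
            paired = paired[paired["age_group"] == age_group]
        rows = []
        for pid, grp in paired.groupby("pair_id", sort=False):
            treated = grp.loc[grp["treatment"] == "ethanol", "sample_id"].iloc[0]
            control = grp.loc[grp["treatment"] == "control", "sample_id"].iloc[0]
            rows.append(
                dict(pair_id=pid, treated_id=treated, control_id=control,
                     sex=grp["sex"].iloc[0], age_group=grp["age_group"].iloc[0])
            )
        return pd.DataFrame(rows, columns=["pair_id", "treated_id", "control_id", "sex", "age_group"])


def read_design(path: str | Path) -> DesignTable:
    t = pd.read_csv(path, dtype=str)
    return DesignTable(t)


def write_design(design: DesignTable, path: str | Path) -> None:
    design.table.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# GeneSetCollection (GMT)
# ---------------------------------------------------------------------------

@dataclass
class GeneSetCollection:
    """Named gene sets (e.g. GO categories) keyed by set_id."""

    sets: dict[str, frozenset[str]]
    names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for sid, members in self.sets.items():
            if not members:
                raise ValidationError(f"gene set {sid!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, set_id: str) -> frozenset[str]:
        return self.sets[set_id]

    def items(self):
        return self.sets.items()


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file; duplicate members within a set are collapsed."""
    sets: dict[str, frozenset[str]] = {}
    names: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"GMT line {lineno}: fewer than 3 tab-separated fields")
            sid, name, *members = fields
            if sid in sets:
                raise FormatError(f"GMT line {lineno}: duplicate set_id {sid!r}")
            sets[sid] = frozenset(m for m in members if m)
            names[sid] = name
    return GeneSetCollection(sets, names)


def write_gmt(coll: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for sid, members in coll.sets.items():
            name = coll.names.get(sid, sid)
            fh.write("\t".join([sid, name, *sorted(members)]) + "\n")
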