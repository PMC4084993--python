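"""Parasite-host-area association tables.

The central empirical input is a long-format table with one row per
(parasite lineage, host species, area) record: which parasite lineage was
found in which host fish in which hydrological area.  A curated table for the
*Margotrema* / Goodeinae system (four parasite lineages, 15 host species
coded a-o, 12 areas coded A-L across central Mexican drainages) ships with
the package; rows of the published source that list two hosts for one area
are expanded to one record per host.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .errors import FormatError, ValidationError

__all__ = ["AssociationTable", "read_association_table", "load_margotrema_table",
           "GOODEINE_TRIBES"]

GOODEINE_TRIBES = frozenset(
    {"Ilyodontini", "Characodontini", "Chapalichthyini", "Girardinichthyini"}
)

_REQUIRED = [
    "parasite_lineage",
    "parasite_rank",
    "host_code",
    "host_species",
    "host_tribe",
    "area_code",
    "area_name",
    "hydrological_system",
]


class AssociationTable:
    """A validated long-format parasite-host-area table."""

    def __init__(self, records: pd.DataFrame):
        df = records.copy()
        missing = [c for c in _REQUIRED if c not in df.columns]
        if missing:
            raise FormatError(f"association table is missing columns: {missing}")
        df = df[_REQUIRED].astype(str)
        if (df.map(lambda v: v.strip() == "")).any().any() or df.isin(
            ["nan", "None"]
        ).any().any():
            raise ValidationError("association table contains empty fields")
        self.records = df.reset_index(drop=True)
        self._validate()

    def _validate(self) -> None:
        df = self.records
        for code in df["host_code"]:
            if not (len(code) == 1 and code.islower() and code.isalpha()):
                raise ValidationError(f"host code {code!r} is not a lowercase letter")
        for code in df["area_code"]:
            if not (len(code) == 1 and code.isupper() and code.isalpha()):
                raise ValidationError(f"area code {code!r} is not an uppercase letter")
        for rank in df["parasite_rank"]:
            if rank not in ("species", "lineage"):
                raise ValidationError(f"unknown parasite rank {rank!r}")
        for tribe in df["host_tribe"]:
            if tribe not in GOODEINE_TRIBES and not tribe.startswith("non-goodeid:"):
                raise ValidationError(f"unknown tribe label {tribe!r}")
        # codes must be a bijection with names
        for code_col, name_col in (
            ("host_code", "host_species"),
            ("area_code", "area_name"),
        ):
            by_code = df.groupby(code_col)[name_col].nunique()
            if (by_code > 1).any():
                bad = by_code[by_code > 1].index.tolist()
                raise ValidationError(f"{code_col} maps to several names: {bad}")
            by_name = df.groupby(name_col)[code_col].nunique()
            if (by_name > 1).any():
                bad = by_name[by_name > 1].index.tolist()
                raise ValidationError(f"{name_col} carries several codes: {bad}")
        triples = df[["parasite_lineage", "host_code", "area_code"]]
        if triples.duplicated().any():
            dup = triples[triples.duplicated()].iloc[0].tolist()
            raise ValidationError(f"duplicate (lineage, host, area) record: {dup}")

    # -- derived views ------------------------------------------------------

    @property
    def n_records(self) -> int:
        return len(self.records)

    @property
    def area_codes(self) -> list[str]:
        return sorted(self.records["area_code"].unique())

    @property
    def host_codes(self) -> list[str]:
        return sorted(self.records["host_code"].unique())

    @property
    def lineages(self) -> list[str]:
        return sorted(self.records["parasite_lineage"].unique())

    @property
    def n_areas(self) -> int:
        return len(self.area_codes)

    @property
    def n_hosts(self) -> int:
        return len(self.host_codes)

    @property
    def n_lineages(self) -> int:
        return len(self.lineages)

    def host_to_tribe(self) -> dict[str, str]:
        return dict(zip(self.records["host_code"], self.records["host_tribe"]))

    def lineage_rank(self) -> dict[str, str]:
        return dict(zip(self.records["parasite_lineage"], self.records["parasite_rank"]))

    def host_names(self) -> dict[str, str]:
        return dict(zip(self.records["host_code"], self.records["host_species"]))

    def terminals(self) -> dict[tuple[str, str], tuple[str, ...]]:
        """Host repertoire per (parasite lineage, area) terminal."""
        out: dict[tuple[str, str], tuple[str, ...]] = {}
        grouped = self.records.groupby(["parasite_lineage", "area_code"])["host_code"]
        for key, hosts in grouped:
            out[key] = tuple(sorted(hosts))
        return out

    def lineage_hosts(self) -> dict[str, tuple[str, ...]]:
        out: dict[str, tuple[str, ...]] = {}
        for lineage, hosts in self.records.groupby("parasite_lineage")["host_code"]:
            out[lineage] = tuple(sorted(set(hosts)))
        return out

    def areas_of_host(self, host_code: str) -> set[str]:
        df = self.records
        return set(df.loc[df["host_code"] == host_code, "area_code"])

    def write(self, path) -> None:
        self.records.to_csv(path, sep="\t", index=False)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"<AssociationTable {self.n_records} records, {self.n_lineages} "
            f"lineages, {self.n_hosts} hosts, {self.n_areas} areas>"
        )


def read_association_table(path) -> AssociationTable:
    """Read a UTF-8 tab-separated association table with header."""
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    except Exception as exc:
        raise FormatError(f"could not read association table: {exc}") from exc
    return AssociationTable(df)


def load_margotrema_table() -> AssociationTable:
    """The packaged *Margotrema* / Goodeinae association table."""
    ref = resources.files("decophylo.data").joinpath("margotrema_associations.tsv")
    with resources.as_file(ref) as path:
        return read_association_table(path)
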