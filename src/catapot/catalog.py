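"""Nutrient catalogs, pathway membership, and organism profiles.

The unit of prediction throughout the package is a *nutrient*: a metabolite
that may be present in the growth medium. Each nutrient carries a structural
class, a carbon count, the set of metabolic pathways it participates in, and
— for complex nutrients such as nucleosides or lipids — a composition in
terms of simpler nutrients. The organism side is a profile: which nutrients
the species transports, whether it encodes the handful of enzymes that gate
fatty-acid and purine catabolism, and its minimal medium.

Catalogs are stored as tab-separated tables (pathway memberships
semicolon-joined, composition as ``id*multiplicity`` pairs) or as JSON with
the same schema; profiles are JSON. Both dialects round-trip exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping


class NutrientClass(Enum):
    """Closed structural/functional classification of nutrients."""

    SUGARS = "Sugars"
    SUGAR_DERIVATIVES = "Sugar derivatives"
    AMINO_ACIDS = "Amino acids"
    AMINO_ACID_DERIVATIVES = "Amino acid derivatives"
    FATTY_ACIDS = "Fatty acids"
    FATTY_ACID_DERIVATIVES = "Fatty acid derivatives"
    PURINES = "Purines"
    PYRIMIDINES = "Pyrimidines"
    INORGANIC = "Inorganic compounds"
    COFACTORS = "Cofactors"
    CELL_BOUNDARY = "Cell boundary"
    ORGANIC = "Organic compounds"

    @classmethod
    def from_label(cls, label: str) -> "NutrientClass":
        for member in cls:
            if member.value == label:
                return member
        raise CatalogError(
            f"unknown nutrient class {label!r}; expected one of "
            + ", ".join(m.value for m in cls)
        )


#: Classes whose members are never catabolized as sole carbon sources.
NG_CLASSES = frozenset(
    {
        NutrientClass.CELL_BOUNDARY,
        NutrientClass.COFACTORS,
        NutrientClass.INORGANIC,
        NutrientClass.PYRIMIDINES,
    }
)

#: Classes whose members are always catabolized (when uptaken).
G_CLASSES = frozenset({NutrientClass.SUGARS, NutrientClass.SUGAR_DERIVATIVES})

#: Classes allowed in randomly generated complex media.
MEDIA_CLASSES = frozenset(
    {
        NutrientClass.SUGARS,
        NutrientClass.FATTY_ACIDS,
        NutrientClass.AMINO_ACIDS,
        NutrientClass.PURINES,
        NutrientClass.PYRIMIDINES,
    }
)


class CatalogError(ValueError):
    """Raised on malformed or inconsistent catalog input."""


@dataclass(frozen=True)
class Nutrient:
    """A medium component: identity, structure, and pathway context.

    ``n_carbons`` is the total carbon count :math:`C_i`. ``components`` is
    the composition of a complex nutrient as ``(nutrient_id, multiplicity)``
    pairs; it is empty exactly when the nutrient is simple.
    """

    id: str
    name: str
    n_carbons: int
    nutrient_class: NutrientClass
    pathways: frozenset[str] = frozenset()
    kegg_id: str | None = None
    components: tuple[tuple[str, int], ...] = ()

    @property
    def is_complex(self) -> bool:
        return len(self.components) > 0

    def __post_init__(self) -> None:
        if self.n_carbons < 0:
            raise CatalogError(f"nutrient {self.id}: negative carbon count")
        for cid, mult in self.components:
            if mult < 1:
                raise CatalogError(
                    f"nutrient {self.id}: component {cid} multiplicity {mult} < 1"
                )


@dataclass(frozen=True)
class OrganismProfile:
    """Species-side inputs to the classification cascade."""

    id: str
    uptaken: frozenset[str] = frozenset()
    has_ec_1_1_1_35: bool = False  # L-3-hydroxyacyl-CoA dehydrogenase (β-oxidation)
    has_ec_2_3_1_16: bool = False  # 3-ketoacyl-CoA thiolase (β-oxidation)
    has_ec_3_5_2_17: bool = False  # 5-hydroxyisourate hydrolase (purine degradation)
    minimal_medium: frozenset[str] = frozenset()
    training_member: bool = True
    anaerobic: bool = False
    glucose_id: str | None = None

    @property
    def can_beta_oxidize(self) -> bool:
        return self.has_ec_1_1_1_35 and self.has_ec_2_3_1_16


class Catalog:
    """Mapping of nutrient id to :class:`Nutrient` with validated composition."""

    def __init__(self, nutrients: Iterable[Nutrient]):
        self._nutrients: dict[str, Nutrient] = {}
        for nut in nutrients:
            if nut.id in self._nutrients:
                raise CatalogError(f"duplicate nutrient id {nut.id}")
            self._nutrients[nut.id] = nut
        self._validate()

    def _validate(self) -> None:
        for nut in self._nutrients.values():
            total = 0
            for cid, mult in nut.components:
                if cid not in self._nutrients:
                    raise CatalogError(
                        f"nutrient {nut.id}: dangling component reference {cid!r}"
                    )
                total += mult * self._nutrients[cid].n_carbons
            if nut.is_complex and total > nut.n_carbons:
                raise CatalogError(
                    f"nutrient {nut.id}: component carbons ({total}) exceed "
                    f"parent carbon count ({nut.n_carbons})"
                )
        # reject composition cycles up front
        for nut in self._nutrients.values():
            if nut.is_complex:
                decompose(nut, self)

    def __getitem__(self, nutrient_id: str) -> Nutrient:
        try:
            return self._nutrients[nutrient_id]
        except KeyError:
            raise CatalogError(f"unknown nutrient id {nutrient_id!r}") from None

    def __contains__(self, nutrient_id: str) -> bool:
        return nutrient_id in self._nutrients

    def __iter__(self):
        return iter(self._nutrients.values())

    def __len__(self) -> int:
        return len(self._nutrients)

    @property
    def ids(self) -> list[str]:
        return list(self._nutrients)

    def of_class(self, nutrient_class: NutrientClass) -> list[Nutrient]:
        return [n for n in self if n.nutrient_class is nutrient_class]


class PathwayCatalog:
    """Pathway id → member nutrient ids, cross-checked against the catalog."""

    def __init__(self, members: Mapping[str, Iterable[str]]):
        self._members = {pid: frozenset(nids) for pid, nids in members.items()}

    def __getitem__(self, pathway_id: str) -> frozenset[str]:
        return self._members[pathway_id]

    def __contains__(self, pathway_id: str) -> bool:
        return pathway_id in self._members

    def __iter__(self):
        return iter(self._members)

    def __len__(self) -> int:
        return len(self._members)

    @property
    def ids(self) -> list[str]:
        return list(self._members)

    def items(self):
        return self._members.items()

    def cross_check(self, catalog: Catalog) -> None:
        """Verify pathway membership is symmetric with ``Nutrient.pathways``."""
        for pid, nids in self._members.items():
            for nid in sorted(nids):
                if nid not in catalog:
                    raise CatalogError(
                        f"pathway {pid}: member nutrient {nid!r} absent from catalog"
                    )
                if pid not in catalog[nid].pathways:
                    raise CatalogError(
                        f"pathway {pid} lists {nid} but the nutrient does not "
                        f"list the pathway"
                    )
        for nut in catalog:
            for pid in nut.pathways:
                if pid not in self._members or nut.id not in self._members[pid]:
                    raise CatalogError(
                        f"nutrient {nut.id} lists pathway {pid} but the pathway "
                        f"table does not list the nutrient"
                    )


def decompose(
    nutrient: Nutrient, catalog: Catalog, _stack: tuple[str, ...] = ()
) -> list[tuple[Nutrient, int]]:
    """Recursively expand a complex nutrient into simple constituents.

    Returns ``(simple nutrient, multiplicity)`` pairs; multiplicities of
    nested compositions multiply through. The composition graph must be a
    DAG — a cycle raises :class:`CatalogError`.
    """
    if nutrient.id in _stack:
        chain = " -> ".join(_stack + (nutrient.id,))
        raise CatalogError(f"cycle in composition graph: {chain}")
    if not nutrient.is_complex:
        return [(nutrient, 1)]
    out: dict[str, int] = {}
    order: list[str] = []
    for cid, mult in nutrient.components:
        child = catalog[cid]
        for simple, m in decompose(child, catalog, _stack + (nutrient.id,)):
            if simple.id not in out:
                out[simple.id] = 0
                order.append(simple.id)
            out[simple.id] += mult * m
    return [(catalog[sid], out[sid]) for sid in order]


# ---------------------------------------------------------------------------
# I/O

_TSV_COLUMNS = ["id", "name", "kegg_id", "n_carbons", "class", "pathways", "components"]


def _parse_components(text: str) -> tuple[tuple[str, int], ...]:
    if not text:
        return ()
    out = []
    for token in text.split(";"):
        token = token.strip()
        if not token:
            continue
        if "*" in token:
            cid, mult = token.split("*", 1)
            out.append((cid.strip(), int(mult)))
        else:
            out.append((token, 1))
    return tuple(out)


def _format_components(components: tuple[tuple[str, int], ...]) -> str:
    return ";".join(cid if mult == 1 else f"{cid}*{mult}" for cid, mult in components)


def _nutrient_from_record(rec: Mapping[str, object]) -> Nutrient:
    components = rec.get("components") or ()
    if isinstance(components, str):
        components = _parse_components(components)
    else:
        components = tuple((str(c), int(m)) for c, m in components)
    pathways = rec.get("pathways") or ()
    if isinstance(pathways, str):
        pathways = [p.strip() for p in pathways.split(";") if p.strip()]
    kegg = rec.get("kegg_id") or None
    return Nutrient(
        id=str(rec["id"]),
        name=str(rec.get("name", rec["id"])),
        kegg_id=str(kegg) if kegg else None,
        n_carbons=int(rec["n_carbons"]),
        nutrient_class=NutrientClass.from_label(str(rec["class"])),
        pathways=frozenset(pathways),
        components=components,
    )


def load_catalog(
    nutrients_path: str | Path, pathways_path: str | Path | None = None
) -> tuple[Catalog, PathwayCatalog]:
    """Load and validate a nutrient catalog and its pathway table.

    ``nutrients_path`` may be TSV (tab-separated, header row) or JSON (a
    list of records with the same field names). The pathway table is TSV
    ``pathway_id<TAB>member;member;...`` or JSON ``{pathway: [members]}``;
    if omitted, the table is reconstructed from per-nutrient memberships.
    Membership must be symmetric between the two files.
    """
    nutrients_path = Path(nutrients_path)
    if not nutrients_path.exists():
        raise FileNotFoundError(nutrients_path)
    if nutrients_path.suffix == ".json":
        records = json.loads(nutrients_path.read_text())
    else:
        records = _read_tsv_records(nutrients_path)
    catalog = Catalog(_nutrient_from_record(rec) for rec in records)

    if pathways_path is None:
        members: dict[str, set[str]] = {}
        for nut in catalog:
            for pid in nut.pathways:
                members.setdefault(pid, set()).add(nut.id)
        pathway_catalog = PathwayCatalog(members)
    else:
        pathways_path = Path(pathways_path)
        if not pathways_path.exists():
            raise FileNotFoundError(pathways_path)
        if pathways_path.suffix == ".json":
            raw = json.loads(pathways_path.read_text())
            pathway_catalog = PathwayCatalog(raw)
        else:
            members = {}
            for line in pathways_path.read_text().splitlines():
                if not line.strip() or line.startswith("#"):
                    continue
                pid, _, rest = line.partition("\t")
                members[pid.strip()] = {
                    t.strip() for t in rest.split(";") if t.strip()
                }
            pathway_catalog = PathwayCatalog(members)
    pathway_catalog.cross_check(catalog)
    return catalog, pathway_catalog


def _read_tsv_records(path: Path) -> list[dict[str, str]]:
    lines = [
        ln for ln in path.read_text().splitlines() if ln.strip() and not ln.startswith("#")
    ]
    if not lines:
        raise CatalogError(f"{path}: empty table")
    header = lines[0].split("\t")
    records = []
    for ln in lines[1:]:
        fields = ln.split("\t")
        records.append(dict(zip(header, fields)))
    return records


def write_catalog(
    catalog: Catalog,
    pathway_catalog: PathwayCatalog,
    nutrients_path: str | Path,
    pathways_path: str | Path,
) -> None:
    """Write the TSV dialect read back by :func:`load_catalog` (exact round-trip)."""
    rows = ["\t".join(_TSV_COLUMNS)]
    for nut in catalog:
        rows.append(
            "\t".join(
                [
                    nut.id,
                    nut.name,
                    nut.kegg_id or "",
                    str(nut.n_carbons),
                    nut.nutrient_class.value,
                    ";".join(sorted(nut.pathways)),
                    _format_components(nut.components),
                ]
            )
        )
    Path(nutrients_path).write_text("\n".join(rows) + "\n")
    prows = [
        f"{pid}\t" + ";".join(sorted(members))
        for pid, members in pathway_catalog.items()
    ]
    Path(pathways_path).write_text("\n".join(prows) + "\n")


def load_profile(path: str | Path) -> OrganismProfile:
    """Read an organism profile from JSON."""
    raw = json.loads(Path(path).read_text())
    return OrganismProfile(
        id=raw["id"],
        uptaken=frozenset(raw.get("uptaken", [])),
        has_ec_1_1_1_35=bool(raw.get("has_ec_1_1_1_35", False)),
        has_ec_2_3_1_16=bool(raw.get("has_ec_2_3_1_16", False)),
        has_ec_3_5_2_17=bool(raw.get("has_ec_3_5_2_17", False)),
        minimal_medium=frozenset(raw.get("minimal_medium", [])),
        training_member=bool(raw.get("training_member", True)),
        anaerobic=bool(raw.get("anaerobic", False)),
        glucose_id=raw.get("glucose_id"),
    )


def write_profile(profile: OrganismProfile, path: str | Path) -> None:
    payload = {
        "id": profile.id,
        "uptaken": sorted(profile.uptaken),
        "has_ec_1_1_1_35": profile.has_ec_1_1_1_35,
        "has_ec_2_3_1_16": profile.has_ec_2_3_1_16,
        "has_ec_3_5_2_17": profile.has_ec_3_5_2_17,
        "minimal_medium": sorted(profile.minimal_medium),
        "training_member": profile.training_member,
        "anaerobic": profile.anaerobic,
        "glucose_id": profile.glucose_id,
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
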