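"""Codebook for categorical working-conditions surveys.

A codebook describes the variables of a survey: ordered categories with
1-based integer codes, thematic group membership, an optional DK/NA
("do not know / no answer") non-response code, and optional published
reference marginal counts. The bundled default codebook describes the
29-variable recode of the 7th Spanish National Survey of Working
Conditions (VII NSWC): a binary accident target V1, a 4-level sector
variable V2, and six 5-level Likert study variables V24-V29 built from
multi-item questionnaire blocks.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import yaml

#: Sentinel integer code for DK/NA non-response in stored tables.
DKNA_CODE = 0

#: Thematic groups a variable may belong to.
GROUPS = (
    "accident",
    "sector",
    "demographics",
    "employment",
    "safety",
    "hygiene",
    "ergonomics",
    "psychosocial",
)


class CodebookError(ValueError):
    """Raised when a codebook document violates its invariants."""


@dataclass(frozen=True)
class VariableDef:
    """Definition of one categorical survey variable.

    Parameters
    ----------
    id : str
        Variable identifier (``V1`` ... ``V29`` in the bundled codebook).
    label : str
        Human-readable description.
    group : str
        Thematic group, one of :data:`GROUPS`.
    categories : tuple of str
        Ordered substantive category labels; integer codes are 1..K in
        this order. DK/NA is *not* listed here.
    dkna : bool
        Whether the variable carries a DK/NA non-response code
        (stored as :data:`DKNA_CODE`).
    reference_counts : tuple of int, optional
        Published marginal counts per substantive category.
    dkna_count : int, optional
        Published DK/NA count (only when ``dkna`` is true).
    reference_alpha : float, optional
        Published Cronbach alpha of the source item block.
    item_block : str, optional
        Identifier of the questionnaire item block this variable
        aggregates (e.g. ``Q28``).
    """

    id: str
    label: str
    group: str
    categories: tuple[str, ...]
    dkna: bool = False
    reference_counts: tuple[int, ...] | None = None
    dkna_count: int | None = None
    reference_alpha: float | None = None
    item_block: str | None = None

    def __post_init__(self) -> None:
        if len(self.categories) < 2:
            raise CodebookError(f"{self.id}: needs >=2 categories")
        if self.group not in GROUPS:
            raise CodebookError(f"{self.id}: unknown group {self.group!r}")
        if self.reference_counts is not None:
            if len(self.reference_counts) != len(self.categories):
                raise CodebookError(
                    f"{self.id}: reference_counts length mismatch"
                )
            if any(c < 0 for c in self.reference_counts):
                raise CodebookError(f"{self.id}: negative reference count")
        if self.dkna_count is not None and not self.dkna:
            raise CodebookError(f"{self.id}: dkna_count without DK/NA code")

    @property
    def n_categories(self) -> int:
        """Number of substantive categories K (codes 1..K)."""
        return len(self.categories)

    @property
    def codes(self) -> tuple[int, ...]:
        """Valid stored codes: 1..K, plus 0 when DK/NA is declared."""
        base = tuple(range(1, self.n_categories + 1))
        return ((DKNA_CODE,) + base) if self.dkna else base

    def is_valid_code(self, code: int) -> bool:
        if code == DKNA_CODE:
            return self.dkna
        return 1 <= code <= self.n_categories

    def code_of(self, label: str) -> int:
        """Map a category label (or ``DK/NA``) to its stored code."""
        if label == "DK/NA":
            if not self.dkna:
                raise CodebookError(f"{self.id}: no DK/NA code declared")
            return DKNA_CODE
        try:
            return self.categories.index(label) + 1
        except ValueError:
            raise CodebookError(
                f"{self.id}: unknown category label {label!r}"
            ) from None


@dataclass(frozen=True)
class ItemBlockDef:
    """Questionnaire item block collapsed into a single study variable."""

    id: str
    target: str
    items: tuple[str, ...]

    @property
    def k(self) -> int:
        return len(self.items)


@dataclass
class Codebook:
    """Ordered collection of :class:`VariableDef` with thematic groups."""

    variables: list[VariableDef]
    item_blocks: dict[str, ItemBlockDef] = field(default_factory=dict)
    name: str = "codebook"
    n_reference: int | None = None

    def __post_init__(self) -> None:
        ids = [v.id for v in self.variables]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise CodebookError(f"duplicate variable id(s): {sorted(dupes)}")
        self._index = {v.id: v for v in self.variables}
        if self.n_reference is not None:
            for v in self.variables:
                if v.reference_counts is None:
                    continue
                total = sum(v.reference_counts) + (v.dkna_count or 0)
                if total != self.n_reference:
                    raise CodebookError(
                        f"{v.id}: reference counts sum to {total}, "
                        f"expected {self.n_reference}"
                    )

    def __contains__(self, var_id: str) -> bool:
        return var_id in self._index

    def __getitem__(self, var_id: str) -> VariableDef:
        try:
            return self._index[var_id]
        except KeyError:
            raise CodebookError(f"unknown variable {var_id!r}") from None

    def __iter__(self):
        return iter(self.variables)

    def __len__(self) -> int:
        return len(self.variables)

    @property
    def ids(self) -> list[str]:
        return [v.id for v in self.variables]

    @property
    def groups(self) -> dict[str, list[str]]:
        """Mapping group name -> variable ids, in codebook order."""
        out: dict[str, list[str]] = {g: [] for g in GROUPS}
        for v in self.variables:
            out[v.group].append(v.id)
        return {g: ids for g, ids in out.items() if ids}

    def cardinality(self, var_id: str) -> int:
        """Total number of modelled categories (substantive + DK/NA)."""
        v = self[var_id]
        return v.n_categories + (1 if v.dkna else 0)


def _parse_variable(doc: dict) -> VariableDef:
    try:
        var_id = doc["id"]
    except KeyError:
        raise CodebookError("variable entry without 'id'") from None
    cats = doc.get("categories") or []
    if not cats:
        raise CodebookError(f"{var_id}: empty category list")
    return VariableDef(
        id=str(var_id),
        label=str(doc.get("label", var_id)),
        group=str(doc.get("group", "")),
        categories=tuple(str(c) for c in cats),
        dkna="dkna_count" in doc or doc.get("dkna", False),
        reference_counts=(
            tuple(int(c) for c in doc["reference_counts"])
            if "reference_counts" in doc
            else None
        ),
        dkna_count=(
            int(doc["dkna_count"]) if "dkna_count" in doc else None
        ),
        reference_alpha=(
            float(doc["reference_alpha"])
            if "reference_alpha" in doc
            else None
        ),
        item_block=doc.get("item_block"),
    )


def load_codebook(source) -> Codebook:
    """Load a codebook from a YAML document.

    Parameters
    ----------
    source : path-like, file object or str
        YAML text with a top-level ``variables`` list and optional
        ``item_blocks`` mapping.
    """
    if hasattr(source, "read"):
        doc = yaml.safe_load(source.read())
    else:
        text = str(source)
        if "\n" not in text and not text.lstrip().startswith("{"):
            with open(text, "r", encoding="utf-8") as fh:
                doc = yaml.safe_load(fh)
        else:
            doc = yaml.safe_load(text)
    if not isinstance(doc, dict) or "variables" not in doc:
        raise CodebookError("codebook document must define 'variables'")
    variables = [_parse_variable(v) for v in doc["variables"]]
    blocks = {}
    for bid, bdoc in (doc.get("item_blocks") or {}).items():
        blocks[bid] = ItemBlockDef(
            id=str(bid),
            target=str(bdoc["target"]),
            items=tuple(str(i) for i in bdoc["items"]),
        )
    return Codebook(
        variables=variables,
        item_blocks=blocks,
        name=str(doc.get("name", "codebook")),
        n_reference=doc.get("n_reference"),
    )


def write_codebook(codebook: Codebook, path) -> None:
    """Serialize a codebook back to YAML (inverse of :func:`load_codebook`)."""
    doc: dict = {"name": codebook.name, "variables": []}
    if codebook.n_reference is not None:
        doc["n_reference"] = codebook.n_reference
    for v in codebook.variables:
        entry: dict = {
            "id": v.id,
            "label": v.label,
            "group": v.group,
            "categories": list(v.categories),
        }
        if v.reference_counts is not None:
            entry["reference_counts"] = list(v.reference_counts)
        if v.dkna:
            entry["dkna_count"] = v.dkna_count if v.dkna_count is not None else 0
        if v.reference_alpha is not None:
            entry["reference_alpha"] = v.reference_alpha
        if v.item_block is not None:
            entry["item_block"] = v.item_block
        doc["variables"].append(entry)
    if codebook.item_blocks:
        doc["item_blocks"] = {
            b.id: {"target": b.target, "items": list(b.items)}
            for b in codebook.item_blocks.values()
        }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False, allow_unicode=True)


def default_codebook() -> Codebook:
    """The bundled VII NSWC codebook (29 variables, published marginals)."""
    ref = importlib.resources.files("accidentbn.data") / "nswc7_codebook.yaml"
    with ref.open("r", encoding="utf-8") as fh:
        return load_codebook(fh)
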