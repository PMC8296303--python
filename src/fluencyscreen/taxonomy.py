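"""Animal lexicon with subcategory membership.

Semantic-fluency scoring needs to know (a) whether a spoken token names an
animal and (b) which semantic subcategories that animal belongs to, because
clusters are runs of consecutive correct responses sharing a subcategory.
Both facts live in a :class:`Taxonomy`: a set of :class:`LexiconEntry`
records, each a canonical animal name, its accepted variants (plurals,
diminutives, regional names) and a non-empty set of subcategory labels.
Entries may belong to several subcategories (a whale is both a sea creature
and a mammal); adjacency between two animals means their subcategory sets
intersect.

The package ships a default English lexicon (~150 animals, ~25
subcategories) modelled on standard semantic-fluency subcategory norms.
Scoring is entirely taxonomy-file-driven, so any language or subcategory
scheme can be substituted by loading a different JSON file.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

__all__ = [
    "UNKNOWN",
    "LexiconEntry",
    "Taxonomy",
    "TaxonomyError",
    "InvalidTokenError",
    "load_taxonomy",
    "write_taxonomy",
    "default_taxonomy",
    "normalize_token",
    "shares_subcategory",
]

#: Marker returned for tokens that match no lexicon entry (non-animal words).
UNKNOWN = "<unknown>"

_DEFAULT_RESOURCE = "animal_taxonomy_en.json"


class TaxonomyError(ValueError):
    """Malformed taxonomy file or violated lexicon invariant."""


class InvalidTokenError(ValueError):
    """Raised for empty or whitespace-only raw tokens."""


def _fold(token: str) -> str:
    return token.strip().casefold()


@dataclass(frozen=True)
class LexiconEntry:
    """One animal: canonical name, accepted variants, subcategory labels."""

    canonical: str
    variants: tuple[str, ...] = ()
    subcategories: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not _fold(self.canonical):
            raise TaxonomyError("canonical token must be non-empty")
        if not self.subcategories:
            raise TaxonomyError(
                f"entry {self.canonical!r} has an empty subcategory set"
            )


class Taxonomy:
    """Immutable lookup structure over a collection of lexicon entries.

    Parameters
    ----------
    entries
        Lexicon entries. Canonicals must be unique (case-insensitively) and
        no token may appear both as a canonical and as a variant of a
        different canonical, nor as a variant of two canonicals.
    """

    def __init__(self, entries: list[LexiconEntry] | tuple[LexiconEntry, ...] = ()):
        self.entries: tuple[LexiconEntry, ...] = tuple(entries)
        self._canonical: dict[str, LexiconEntry] = {}
        self._variant: dict[str, str] = {}
        for entry in self.entries:
            key = _fold(entry.canonical)
            if key in self._canonical:
                raise TaxonomyError(f"duplicate canonical entry {entry.canonical!r}")
            self._canonical[key] = entry
        for entry in self.entries:
            for variant in entry.variants:
                vkey = _fold(variant)
                ckey = _fold(entry.canonical)
                if vkey in self._canonical and vkey != ckey:
                    raise TaxonomyError(
                        f"token {variant!r} is both a canonical and a variant "
                        f"of {entry.canonical!r}"
                    )
                if vkey in self._variant and self._variant[vkey] != ckey:
                    raise TaxonomyError(
                        f"variant {variant!r} maps to two canonicals"
                    )
                self._variant[vkey] = ckey
        self.subcategory_registry: frozenset[str] = frozenset(
            sub for entry in self.entries for sub in entry.subcategories
        )

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, token: str) -> bool:
        key = _fold(token)
        return key in self._canonical or key in self._variant

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Taxonomy):
            return NotImplemented
        return self.entries == other.entries

    def canonical_of(self, token: str) -> str | None:
        """Canonical form of *token*, or None if it is not in the lexicon."""
        key = _fold(token)
        if key in self._canonical:
            return self._canonical[key].canonical
        if key in self._variant:
            return self._canonical[self._variant[key]].canonical
        return None

    def subcategories_of(self, canonical: str) -> frozenset[str]:
        key = _fold(canonical)
        if key not in self._canonical:
            raise TaxonomyError(f"{canonical!r} is not a canonical lexicon entry")
        return self._canonical[key].subcategories

    def members_of(self, subcategory: str) -> tuple[str, ...]:
        """Canonical names belonging to *subcategory*, in entry order."""
        return tuple(
            e.canonical for e in self.entries if subcategory in e.subcategories
        )


def load_taxonomy(path: str | Path) -> Taxonomy:
    """Load a taxonomy from a JSON file.

    The file is a top-level list of objects
    ``{"canonical": str, "variants": [str], "subcategories": [str]}``.
    Raises :class:`TaxonomyError` naming the offending entry on schema or
    uniqueness violations.
    """
    with open(path, encoding="utf-8") as fh:
        try:
            raw = json.load(fh)
        except json.JSONDecodeError as exc:
            raise TaxonomyError(f"{path}: not valid JSON ({exc})") from exc
    return _from_obj(raw, source=str(path))


def _from_obj(raw: object, source: str = "<memory>") -> Taxonomy:
    if not isinstance(raw, list):
        raise TaxonomyError(f"{source}: top level must be a list of entries")
    entries = []
    for i, item in enumerate(raw):
        if not isinstance(item, dict) or "canonical" not in item:
            raise TaxonomyError(f"{source}: entry #{i} lacks a 'canonical' field")
        try:
            entries.append(
                LexiconEntry(
                    canonical=str(item["canonical"]),
                    variants=tuple(str(v) for v in item.get("variants", [])),
                    subcategories=frozenset(
                        str(s) for s in item.get("subcategories", [])
                    ),
                )
            )
        except TaxonomyError as exc:
            raise TaxonomyError(f"{source}: entry #{i}: {exc}") from exc
    return Taxonomy(entries)


def write_taxonomy(taxonomy: Taxonomy, path: str | Path) -> None:
    """Write *taxonomy* back to the documented JSON schema (round-trips)."""
    obj = [
        {
            "canonical": e.canonical,
            "variants": list(e.variants),
            "subcategories": sorted(e.subcategories),
        }
        for e in taxonomy.entries
    ]
    Path(path).write_text(
        json.dumps(obj, indent=1, ensure_ascii=False, sort_keys=True),
        encoding="utf-8",
    )


def default_taxonomy() -> Taxonomy:
    """The bundled default English animal lexicon."""
    text = (
        resources.files("fluencyscreen") / "data" / _DEFAULT_RESOURCE
    ).read_text(encoding="utf-8")
    return _from_obj(json.loads(text), source=_DEFAULT_RESOURCE)


def normalize_token(raw: str, taxonomy: Taxonomy) -> str:
    """Map a raw transcribed token to its canonical lexicon form.

    Matching is exact after whitespace trimming and case folding, first
    against canonicals, then variants. Tokens absent from the lexicon return
    :data:`UNKNOWN`. Empty tokens raise :class:`InvalidTokenError`.
    """
    key = _fold(raw)
    if not key:
        raise InvalidTokenError("empty or whitespace-only token")
    canonical = taxonomy.canonical_of(key)
    return canonical if canonical is not None else UNKNOWN


def shares_subcategory(a: str, b: str, taxonomy: Taxonomy) -> bool:
    """True iff canonical animals *a* and *b* share at least one subcategory."""
    return bool(taxonomy.subcategories_of(a) & taxonomy.subcategories_of(b))
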