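"""rCRS-relative variant-string haplotypes.

Human mtDNA population studies conventionally report a sample's control-region
sequence as the list of positions at which it differs from the revised
Cambridge Reference Sequence (rCRS, positions 1..16569).  This module parses
that notation, normalizes it into :class:`Variant`/:class:`Haplotype` objects,
counts pairwise differences under an explicit :class:`DistancePolicy`, and
ships the 81-sample El Jadida (Morocco) table as a packaged fixture.

Notation dialect
----------------
``129``        transition at the position (HVRI positions are printed minus
               16000 and restored on parsing)
``184C``       transversion to the stated base
``318A/C``     ambiguous / heteroplasmic call; both bases retained
``309.1``      C-insertion after the position (``.2`` = second inserted base);
               an explicit base may follow, e.g. ``309.1T``
``196insT``    insertion spelled with ``ins``; normalized to ``196.1T``
``193del``     deletion (``193d`` also accepted)
``0``          identity to the rCRS in that region
"""

from __future__ import annotations

import csv
import hashlib
import re
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "HVRI",
    "HVRII",
    "CODING",
    "REGIONS",
    "SUBSTITUTION",
    "INSERTION",
    "DELETION",
    "Variant",
    "Haplotype",
    "DistancePolicy",
    "VariantParseError",
    "parse_variant_token",
    "parse_region_string",
    "parse_haplotype_row",
    "render_variant",
    "render_region_string",
    "haplotype_distance",
    "distance_matrix",
    "distinct_haplotypes",
    "segregating_sites",
    "ambiguous_site_exclusions",
    "read_population_table",
    "write_population_table",
    "load_eljadida_fixture",
]

#: Region labels.  ``CODING`` covers the coding-region segments typed in
#: possible-H samples (the "other polymorphisms" column of a population table).
HVRI = "HVRI"
HVRII = "HVRII"
CODING = "CODING"
REGIONS = (HVRI, HVRII, CODING)

SUBSTITUTION = "substitution"
INSERTION = "insertion"
DELETION = "deletion"

RCRS_LENGTH = 16569

#: Printed HVRI positions below this value are offsets to be restored by +16000.
_HVRI_OFFSET = 16000


class VariantParseError(ValueError):
    """A variant token does not match the notation grammar."""


@dataclass(frozen=True, order=True)
class Variant:
    """One rCRS-relative sequence change.

    Parameters
    ----------
    position : int
        rCRS position, 1..16569 (HVRI offsets already restored).
    kind : str
        One of ``substitution``, ``insertion``, ``deletion``.
    derived : tuple of str
        Derived base(s).  Empty for a bare transition (the notation names no
        base; the change is the transition partner of the reference).  Two
        bases encode an ambiguous/heteroplasmic call such as ``318A/C``; the
        printed order is preserved for round-tripping.
    insert_index : int
        1-based index of an inserted base (``309.2`` -> 2); 0 otherwise.
    ref : str
        Reference base when the notation states one (it never does in the
        fixture dialect); kept for interoperability.
    """

    position: int
    kind: str = SUBSTITUTION
    derived: tuple[str, ...] = ()
    insert_index: int = 0
    ref: str = ""

    def __post_init__(self) -> None:
        if not 1 <= self.position <= RCRS_LENGTH:
            raise VariantParseError(
                f"position {self.position} outside rCRS range 1..{RCRS_LENGTH}"
            )
        if self.kind not in (SUBSTITUTION, INSERTION, DELETION):
            raise VariantParseError(f"unknown variant kind {self.kind!r}")
        if (self.insert_index > 0) != (self.kind == INSERTION):
            raise VariantParseError(
                "insert_index must be positive exactly for insertions"
            )
        if self.kind == INSERTION and not self.derived:
            raise VariantParseError("insertion requires at least one base")

    @property
    def key(self) -> tuple[int, int, str]:
        """Identity of the variant site: (position, insert_index, kind)."""
        return (self.position, self.insert_index, self.kind)

    @property
    def state(self) -> frozenset:
        """Allele state used for comparisons (unordered)."""
        return frozenset(self.derived)

    @property
    def is_ambiguous(self) -> bool:
        return len(self.derived) > 1


_TOKEN_INS_DOT = re.compile(r"(\d+)\.(\d+)([ACGT]*)\Z")
_TOKEN_INS_WORD = re.compile(r"(\d+)ins([ACGT]+)\Z", re.IGNORECASE)
_TOKEN_DEL = re.compile(r"(\d+)(?:del|d)\Z", re.IGNORECASE)
_TOKEN_SUB = re.compile(r"(\d+)([ACGT])?(?:/([ACGT]))?\Z")


def _restore_offset(printed: int, region: str) -> int:
    if region == HVRI and printed < _HVRI_OFFSET:
        return printed + _HVRI_OFFSET
    return printed


def parse_variant_token(token: str, region: str) -> Variant:
    """Parse one variant token of the population-table dialect.

    >>> parse_variant_token("129", "HVRI").position
    16129
    >>> parse_variant_token("309.2", "HVRII").insert_index
    2
    """
    if region not in REGIONS:
        raise ValueError(f"unknown region {region!r}")
    tok = token.strip()
    if not tok:
        raise VariantParseError("empty variant token")

    if m := _TOKEN_DEL.match(tok):
        pos = _restore_offset(int(m.group(1)), region)
        return Variant(pos, DELETION)
    if m := _TOKEN_INS_WORD.match(tok):
        pos = _restore_offset(int(m.group(1)), region)
        return Variant(pos, INSERTION, tuple(m.group(2).upper()), insert_index=1)
    if m := _TOKEN_INS_DOT.match(tok):
        pos = _restore_offset(int(m.group(1)), region)
        bases = m.group(3) or "C"
        return Variant(pos, INSERTION, tuple(bases.upper()), insert_index=int(m.group(2)))
    if m := _TOKEN_SUB.match(tok):
        pos = _restore_offset(int(m.group(1)), region)
        derived = tuple(b for b in (m.group(2), m.group(3)) if b)
        if len(derived) == 2 and derived[0] == derived[1]:
            raise VariantParseError(f"degenerate ambiguity in token {token!r}")
        return Variant(pos, SUBSTITUTION, derived)
    raise VariantParseError(f"cannot parse variant token {token!r}")


def render_variant(v: Variant, region: str) -> str:
    """Canonical string form of a variant (inverse of the parser)."""
    pos = v.position - _HVRI_OFFSET if region == HVRI and v.position > _HVRI_OFFSET else v.position
    if v.kind == DELETION:
        return f"{pos}del"
    if v.kind == INSERTION:
        bases = "".join(v.derived)
        suffix = "" if bases == "C" else bases
        return f"{pos}.{v.insert_index}{suffix}"
    return f"{pos}{'/'.join(v.derived)}"


def parse_region_string(text: str, region: str) -> frozenset[Variant]:
    """Parse a whitespace-separated variant string; ``0`` (or blank) = rCRS."""
    text = text.strip()
    if text in ("", "0"):
        return frozenset()
    variants = [parse_variant_token(tok, region) for tok in text.split()]
    keys = [v.key for v in variants]
    if len(set(keys)) != len(keys):
        dupes = sorted({k for k in keys if keys.count(k) > 1})
        raise VariantParseError(f"duplicate variant keys in {region}: {dupes}")
    if region == HVRI:
        for v in variants:
            if v.position <= _HVRI_OFFSET:
                raise VariantParseError(
                    f"HVRI variant at position {v.position} outside the region"
                )
    return frozenset(variants)


def render_region_string(variants: Iterable[Variant], region: str) -> str:
    """Canonical variant string for one region (``0`` when rCRS-identical)."""
    toks = sorted(
        ((v.position, v.insert_index, v.kind, render_variant(v, region)) for v in variants)
    )
    return " ".join(t[3] for t in toks) if toks else "0"


@dataclass(frozen=True)
class Haplotype:
    """A sample's rCRS-relative variants, per region.

    A region key absent from ``region_variants`` means the region was not
    typed for this sample, which is distinct from typed-and-identical-to-rCRS
    (present with an empty set).  The distinction matters when scoring
    coding-region haplogroup motifs: unobserved is not absent.
    """

    sample_id: str
    region_variants: Mapping[str, frozenset[Variant]]
    haplogroup_label: str | None = None
    population: str = ""

    def variants(self, region: str) -> frozenset[Variant]:
        return self.region_variants.get(region, frozenset())

    def is_typed(self, region: str) -> bool:
        return region in self.region_variants


def parse_haplotype_row(
    sample_id: str,
    hvri_text: str,
    hvrii_text: str,
    other_text: str = "",
    haplogroup: str | None = None,
    population: str = "",
) -> Haplotype:
    """Build a Haplotype from the three variant-string columns of a table row.

    ``other_text`` is the coding-segment column; an empty string means the
    coding segments were not typed (the column is only filled for samples in
    which coding positions were assayed).
    """
    regions: dict[str, frozenset[Variant]] = {
        HVRI: parse_region_string(hvri_text, HVRI),
        HVRII: parse_region_string(hvrii_text, HVRII),
    }
    if other_text.strip():
        regions[CODING] = parse_region_string(other_text, CODING)
    return Haplotype(
        sample_id=sample_id,
        region_variants=regions,
        haplogroup_label=haplogroup,
        population=population,
    )


# ---------------------------------------------------------------------------
# Distance policy and pairwise differences
# ---------------------------------------------------------------------------

#: Ambiguity-handling modes for pairwise comparisons.
AMBIGUITY_MODES = ("state", "overlap", "missing")


@dataclass(frozen=True)
class DistancePolicy:
    """Conventions for counting differences between two haplotypes.

    Attributes
    ----------
    range_start, range_end : int
        Inclusive rCRS window; variants outside are ignored.  The default is
        the HVRI reading frame 16024..16365 used for the diversity analyses.
    count_indels : bool
        Include insertions/deletions in difference counts.  Off by default
        (the common sequence-data convention).
    ambiguous : str
        ``"state"``   - an ambiguous call is its own character state; two
                        calls differ whenever their base sets differ (the
                        default; matches the reference results).
        ``"overlap"`` - two calls at a key agree when their base sets
                        intersect.
        ``"missing"`` - ambiguous calls are treated as missing data and
                        contribute no differences.
    excluded_positions : frozenset of int
        Positions removed before any counting.  16519, a mutational hotspot,
        is excluded by default.
    max_ambiguous_fraction : float
        Dataset-level site filter: sites at which more than this fraction of
        samples carry an ambiguous call are excluded from counting (see
        :func:`ambiguous_site_exclusions`).  0.05 mirrors the usual
        allowed-missing-per-site threshold.
    """

    range_start: int = 16024
    range_end: int = 16365
    count_indels: bool = False
    ambiguous: str = "state"
    excluded_positions: frozenset[int] = frozenset({16519})
    max_ambiguous_fraction: float = 0.05

    def __post_init__(self) -> None:
        if self.range_start >= self.range_end:
            raise ValueError("range_start must be < range_end")
        if self.ambiguous not in AMBIGUITY_MODES:
            raise ValueError(f"ambiguous must be one of {AMBIGUITY_MODES}")

    def admits(self, v: Variant) -> bool:
        """Whether a variant participates in counting under this policy."""
        if not self.range_start <= v.position <= self.range_end:
            return False
        if v.position in self.excluded_positions:
            return False
        if v.kind in (INSERTION, DELETION) and not self.count_indels:
            return False
        return True

    def site_map(self, h: Haplotype, region: str) -> dict[tuple, frozenset]:
        """Admitted variants of one region as a key -> allele-state mapping."""
        return {v.key: v.state for v in h.variants(region) if self.admits(v)}

    def with_excluded(self, positions: Iterable[int]) -> "DistancePolicy":
        return replace(self, excluded_positions=self.excluded_positions | frozenset(positions))

    def for_dataset(self, haplotypes: Sequence[Haplotype], region: str = HVRI) -> "DistancePolicy":
        """Policy with the dataset-level ambiguous-site filter applied."""
        return self.with_excluded(ambiguous_site_exclusions(haplotypes, self, region))


def ambiguous_site_exclusions(
    haplotypes: Sequence[Haplotype], policy: DistancePolicy, region: str = HVRI
) -> frozenset[int]:
    """Positions at which ambiguous calls exceed the policy's allowed fraction.

    Sites where a large share of samples carry heteroplasmic/ambiguous calls
    carry no reliable pairwise signal and are removed from the analysis, the
    same way sites with too much missing data are dropped from sequence data.
    """
    if not haplotypes:
        return frozenset()
    n = len(haplotypes)
    counts: dict[int, int] = {}
    for h in haplotypes:
        for v in h.variants(region):
            if policy.admits(v) and v.is_ambiguous:
                counts[v.position] = counts.get(v.position, 0) + 1
    return frozenset(p for p, c in counts.items() if c / n > policy.max_ambiguous_fraction)


def _states_differ(a: frozenset | None, b: frozenset | None, mode: str) -> bool:
    if a is None and b is None:
        return False
    if mode == "missing":
        if (a is not None and len(a) > 1) or (b is not None and len(b) > 1):
            return False
        return a != b
    if a is None or b is None:
        return True
    if mode == "overlap":
        return a != b and not (a & b)
    return a != b  # "state"


def haplotype_distance(
    a: Haplotype, b: Haplotype, policy: DistancePolicy | None = None, region: str = HVRI
) -> int:
    """Number of admitted variant keys at which two haplotypes differ.

    Symmetric; zero iff the two admitted variant maps are equivalent under
    the policy's ambiguity mode.
    """
    policy = policy or DistancePolicy()
    sa = policy.site_map(a, region)
    sb = policy.site_map(b, region)
    return sum(
        _states_differ(sa.get(k), sb.get(k), policy.ambiguous) for k in set(sa) | set(sb)
    )


def distance_matrix(
    haplotypes: Sequence[Haplotype], policy: DistancePolicy | None = None, region: str = HVRI
):
    """Full pairwise-difference matrix as a numpy array of shape (n, n)."""
    import numpy as np

    policy = policy or DistancePolicy()
    maps = [policy.site_map(h, region) for h in haplotypes]
    n = len(maps)
    d = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        for j in range(i + 1, n):
            dij = sum(
                _states_differ(maps[i].get(k), maps[j].get(k), policy.ambiguous)
                for k in set(maps[i]) | set(maps[j])
            )
            d[i, j] = d[j, i] = dij
    return d


def _signature(h: Haplotype, policy: DistancePolicy, region: str) -> frozenset:
    return frozenset(policy.site_map(h, region).items())


def distinct_haplotypes(
    haplotypes: Sequence[Haplotype], policy: DistancePolicy | None = None, region: str = HVRI
) -> dict[frozenset, int]:
    """Multiset of distinct haplotype signatures under the policy."""
    policy = policy or DistancePolicy()
    out: dict[frozenset, int] = {}
    for h in haplotypes:
        sig = _signature(h, policy, region)
        out[sig] = out.get(sig, 0) + 1
    return out


def segregating_sites(
    haplotypes: Sequence[Haplotype], policy: DistancePolicy | None = None, region: str = HVRI
) -> int:
    """Number of admitted variant keys segregating in the sample."""
    policy = policy or DistancePolicy()
    keys = set()
    for h in haplotypes:
        keys.update(policy.site_map(h, region))
    return len(keys)


# ---------------------------------------------------------------------------
# Population-table I/O and the packaged fixture
# ---------------------------------------------------------------------------

_COLUMNS = ("sample_id", "population", "HVRI", "HVRII", "OTHER", "haplogroup")

#: SHA-256 of the packaged El Jadida table; guards against silent corruption.
ELJADIDA_SHA256 = "cd51bbc768792223e227d167a115e0613d9a2cd4af6bd58b9ba6507ca1a10d2c"


class FixtureIntegrityError(RuntimeError):
    """The packaged fixture does not match its recorded checksum."""


def read_population_table(path_or_lines) -> list[Haplotype]:
    """Read a TSV population table into haplotypes.

    Columns: sample_id, population, HVRI, HVRII, OTHER, haplogroup (the last
    two optional).  Lines starting with ``#`` are comments.
    """
    if isinstance(path_or_lines, (str, Path)):
        with open(path_or_lines, newline="") as fh:
            lines = fh.readlines()
    else:
        lines = list(path_or_lines)
    rdr = csv.DictReader((l for l in lines if not l.startswith("#")), delimiter="\t")
    out = []
    for row in rdr:
        out.append(
            parse_haplotype_row(
                row["sample_id"],
                row.get("HVRI", ""),
                row.get("HVRII", ""),
                row.get("OTHER", "") or "",
                haplogroup=(row.get("haplogroup") or None),
                population=row.get("population", ""),
            )
        )
    return out


def write_population_table(haplotypes: Sequence[Haplotype], path, header_comment: str = "") -> None:
    with open(path, "w", newline="") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_COLUMNS)
        for h in haplotypes:
            w.writerow(
                [
                    h.sample_id,
                    h.population,
                    render_region_string(h.variants(HVRI), HVRI),
                    render_region_string(h.variants(HVRII), HVRII),
                    render_region_string(h.variants(CODING), CODING) if h.is_typed(CODING) else "",
                    h.haplogroup_label or "",
                ]
            )


def _fixture_bytes() -> bytes:
    return resources.files("mthaplopop.data").joinpath("eljadida.tsv").read_bytes()


def load_eljadida_fixture() -> list[Haplotype]:
    """The 81 El Jadida control-region haplotypes with published labels.

    Verifies the packaged file against a recorded SHA-256 before parsing.
    """
    raw = _fixture_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != ELJADIDA_SHA256:
        raise FixtureIntegrityError(
            f"eljadida.tsv checksum mismatch: {digest} != {ELJADIDA_SHA256}"
        )
    haps = read_population_table(raw.decode().splitlines(keepends=True))
    if len(haps) != 81:
        raise FixtureIntegrityError(f"expected 81 fixture haplotypes, found {len(haps)}")
    return haps
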