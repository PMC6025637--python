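"""Column conservation profiles and declarative diagnostic-residue grouping.

Positions in this module are mature-reference positions: 1-based residue
numbers on the ungapped reference mature chain (the 175-residue A-type
chain by convention), carried onto other rows through the alignment column
map.  That single numbering is what makes rules like "Asn78 + Glu82 +
Asp96 -> group IC" meaningful across isoforms whose own N-termini differ by
a residue or two.

Rules are data, not code: the packaged ``group_rules.tsv`` table encodes the
diagnostic residues of the family's sequence groups (IA, IB, IC, ID with
subgroups, IE) and can be curated without touching the classifier.  Matching
is deterministic: parent-level rules are tried most-specific-first, and
subgroup rules only after their parent matched.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

from .align import GAP, MultipleAlignment
from .errors import RuleError

__all__ = [
    "ColumnProfile",
    "GroupRule",
    "GroupAssignment",
    "column_profile",
    "profile_table",
    "count_region_variants",
    "load_group_rules",
    "default_group_rules",
    "classify_group",
    "clade_from_group",
    "check_hotspots",
]

_AROMATIC = set("FWY")


@dataclass(frozen=True)
class ColumnProfile:
    column: int  # 0-based alignment column
    frequencies: dict[str, float]  # gaps excluded; sums to 1
    information: float  # bits
    substitutive: bool  # more than one residue observed


@dataclass(frozen=True)
class GroupRule:
    label: str
    required: dict[int, frozenset]  # mature-reference position -> allowed residues
    priority: int = 0
    parent: str | None = None


@dataclass
class GroupAssignment:
    isoform_id: str
    label: str  # matched label or "unassigned"
    evidence: list[dict] = field(default_factory=list)


def column_profile(
    msa: MultipleAlignment, small_sample_correction: bool = False
) -> list[ColumnProfile]:
    """Per-column residue frequencies and information content.

    Information = log2(20) - Shannon entropy of the gap-free column
    distribution, optionally minus the Basharin small-sample correction
    (s-1)/(2 ln2 n); family-scale alignments (~40 rows) make the correction
    minor, so it is off by default.
    """
    if not msa.rows:
        raise ValueError("empty alignment")
    out = []
    for col in range(msa.n_columns):
        counts: dict[str, int] = {}
        for r in msa.rows:
            c = r[col]
            if c != GAP:
                counts[c] = counts.get(c, 0) + 1
        n = sum(counts.values())
        freqs = {c: v / n for c, v in counts.items()} if n else {}
        entropy = -sum(f * math.log2(f) for f in freqs.values()) if freqs else 0.0
        info = math.log2(20) - entropy
        if small_sample_correction and n > 0:
            info -= (len(freqs) - 1) / (2.0 * math.log(2) * n)
        out.append(
            ColumnProfile(
                column=col,
                frequencies=freqs,
                information=max(info, 0.0),
                substitutive=len(freqs) > 1,
            )
        )
    return out


def profile_table(profiles: list[ColumnProfile]) -> pd.DataFrame:
    """Logo-ready data matrix: one row per column, one field per residue."""
    residues = sorted({c for p in profiles for c in p.frequencies})
    rows = []
    for p in profiles:
        row = {"column": p.column + 1, "information": p.information,
               "substitutive": p.substitutive}
        for aa in residues:
            row[aa] = p.frequencies.get(aa, 0.0)
        rows.append(row)
    return pd.DataFrame(rows)


def count_region_variants(
    msa: MultipleAlignment,
    region: tuple[int, int] = (1, 27),
    n_type: str | None = None,
) -> int:
    """Distinct subsequences over a mature-reference position window.

    ``region`` is inclusive in reference numbering; gaps within the window
    are retained as characters, so an indel variant counts as its own
    variant.  ``n_type`` restricts the count to rows whose ungapped sequence
    starts with that residue type ('A' or 'S').
    """
    colmap = msa.reference_column_map()
    lo, hi = region
    try:
        cols = [colmap[p] for p in range(lo, hi + 1)]
    except KeyError as exc:
        raise RuleError(f"region position {exc} outside the reference mature chain")
    variants = set()
    for r in msa.rows:
        if n_type is not None:
            ungapped = r.replace(GAP, "")
            if not ungapped.startswith(n_type):
                continue
        variants.add("".join(r[c] for c in cols))
    return len(variants)


def _parse_positions(spec: str) -> dict[int, frozenset]:
    out = {}
    for chunk in spec.split(";"):
        pos, allowed = chunk.split(":")
        out[int(pos)] = frozenset(allowed)
    return out


def load_group_rules(path) -> list[GroupRule]:
    """Read a rule table (TSV: label, parent, priority, positions)."""
    df = pd.read_csv(path, sep="\t", dtype={"label": str, "parent": str})
    rules = []
    for _, row in df.iterrows():
        parent = row.get("parent")
        if isinstance(parent, float) and math.isnan(parent):
            parent = None
        rules.append(
            GroupRule(
                label=row["label"],
                parent=parent or None,
                priority=int(row["priority"]),
                required=_parse_positions(row["positions"]),
            )
        )
    return rules


def default_group_rules() -> list[GroupRule]:
    """The packaged diagnostic-residue rules of the actinoporin family."""
    with resources.as_file(
        resources.files("actinofam.data").joinpath("group_rules.tsv")
    ) as p:
        return load_group_rules(p)


def _observe(row: str, colmap: dict[int, int], pos: int) -> str:
    try:
        return row[colmap[pos]]
    except KeyError:
        raise RuleError(f"rule position {pos} has no alignment column for the reference")


def _match_rule(row: str, colmap: dict[int, int], rule: GroupRule) -> tuple[bool, list[dict]]:
    evidence = []
    ok = True
    for pos in sorted(rule.required):
        obs = _observe(row, colmap, pos)
        hit = obs in rule.required[pos]
        ok &= hit
        evidence.append(
            {
                "label": rule.label,
                "position": pos,
                "allowed": "".join(sorted(rule.required[pos])),
                "observed": obs,
                "matched": hit,
            }
        )
    return ok, evidence


def classify_group(
    isoform_id: str,
    aligned_row: str,
    msa: MultipleAlignment,
    rules: list[GroupRule] | None = None,
) -> GroupAssignment:
    """Assign an aligned isoform row to a diagnostic-residue group.

    Parent-level rules are evaluated most-specific-first (more required
    positions win; ties by priority, then declaration order); the first full
    match wins.  Subgroup rules are evaluated only after their parent
    matched, under the same ordering.  A row matching nothing is labelled
    "unassigned" and still carries the full evidence trail.
    """
    rules = rules if rules is not None else default_group_rules()
    colmap = msa.reference_column_map()
    parents = [r for r in rules if r.parent is None]
    order = sorted(
        range(len(parents)),
        key=lambda i: (-len(parents[i].required), parents[i].priority, i),
    )
    evidence: list[dict] = []
    for i in order:
        rule = parents[i]
        ok, ev = _match_rule(aligned_row, colmap, rule)
        evidence.extend(ev)
        if ok:
            label = rule.label
            subs = [r for r in rules if r.parent == rule.label]
            sub_order = sorted(
                range(len(subs)),
                key=lambda i: (-len(subs[i].required), subs[i].priority, i),
            )
            for j in sub_order:
                sok, sev = _match_rule(aligned_row, colmap, subs[j])
                evidence.extend(sev)
                if sok:
                    label = subs[j].label
                    break
            return GroupAssignment(isoform_id=isoform_id, label=label, evidence=evidence)
    return GroupAssignment(isoform_id=isoform_id, label="unassigned", evidence=evidence)


_GROUP_TO_CLADE = {
    "IA": "Clade I",
    "IB": "Clade I",
    "ID": "Clade I",
    "ID1": "Clade I",
    "ID3": "Clade I",
    "ID4": "Clade I",
    "IC": "Clade II",
    "ID2": "Clade III",
}


def clade_from_group(label: str) -> str | None:
    """Electrostatic-similarity clade implied by a sequence group label.

    The family's potential-similarity clustering maps onto the sequence
    groups: IA/IB/ID (minus ID2) fall in Clade I, IC forms Clade II, and ID2
    falls in Clade III; unassigned groups have no implied clade.
    """
    return _GROUP_TO_CLADE.get(label)


def check_hotspots(
    isoform_id: str,
    aligned_row: str,
    msa: MultipleAlignment,
    poc_positions: tuple[int, ...] = (112,),
) -> dict:
    """Conservation flags for the functionally critical sites.

    Checks the "pseudo-string" Ser30-Arg31-Lys32 triplet, Lys77, presence of
    an RGD motif anywhere in the ungapped chain, and aromaticity (F/W/Y) at
    the configurable phosphocholine-binding (POC) site positions.
    """
    colmap = msa.reference_column_map()
    obs = {p: _observe(aligned_row, colmap, p) for p in (30, 31, 32, 77, *poc_positions)}
    ungapped = aligned_row.replace(GAP, "")
    return {
        "id": isoform_id,
        "srk_30_32": obs[30] == "S" and obs[31] == "R" and obs[32] == "K",
        "k77": obs[77] == "K",
        "rgd": "RGD" in ungapped,
        "poc_aromatic": all(obs[p] in _AROMATIC for p in poc_positions),
    }
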