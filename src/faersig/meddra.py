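"""PT -> SOC lookups from a user-supplied MedDRA-style hierarchy table.

MedDRA itself is licensed and is never bundled; users point the pipeline
at their own tab-separated ``pt\\tsoc`` export.  Lookup is exact after
case-folding and whitespace collapsing — no fuzzy matching, so results
are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

UNMAPPED = "UNMAPPED"


class HierarchyConflictError(Exception):
    """A PT is assigned to more than one primary SOC."""

    def __init__(self, conflicts: dict[str, set[str]]) -> None:
        self.conflicts = conflicts
        listing = "; ".join(
            f"{pt!r} -> {sorted(socs)}" for pt, socs in sorted(conflicts.items())
        )
        super().__init__(f"conflicting primary SOC assignments: {listing}")


def _normalize_pt(pt: str) -> str:
    return " ".join(pt.casefold().split())


@dataclass
class MeddraHierarchy:
    """Case-insensitive PT -> primary SOC mapping."""

    pt_to_soc: dict[str, str] = field(default_factory=dict)
    version_label: str = ""
    miss_tally: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.pt_to_soc)


def load_hierarchy(path: str | Path, version_label: str = "") -> MeddraHierarchy:
    """Load a tab-separated hierarchy file with columns ``pt`` and ``soc``.

    Extra columns (hlt, hlgt, ...) are ignored.  Duplicate identical rows
    collapse; a PT mapped to two different SOCs raises
    :class:`HierarchyConflictError` listing every conflict.
    """
    mapping: dict[str, str] = {}
    conflicts: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        header_line = fh.readline()
        if not header_line:
            return MeddraHierarchy({}, version_label)
        header = [h.strip().lower() for h in header_line.rstrip("\n").split("\t")]
        if "pt" not in header or "soc" not in header:
            raise ValueError(f"{path}: hierarchy header must contain pt and soc columns")
        pt_col, soc_col = header.index("pt"), header.index("soc")
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            pt = _normalize_pt(parts[pt_col])
            soc = parts[soc_col].strip()
            if not pt or not soc:
                continue
            if pt in mapping and mapping[pt] != soc:
                conflicts.setdefault(pt, {mapping[pt]}).add(soc)
            else:
                mapping[pt] = soc
    if conflicts:
        raise HierarchyConflictError(conflicts)
    return MeddraHierarchy(mapping, version_label)


def soc_of(pt: str, hierarchy: MeddraHierarchy) -> str:
    """Primary SOC for a PT, or :data:`UNMAPPED` (misses are tallied)."""
    soc = hierarchy.pt_to_soc.get(_normalize_pt(pt))
    if soc is None:
        hierarchy.miss_tally[pt] = hierarchy.miss_tally.get(pt, 0) + 1
        return UNMAPPED
    return soc
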