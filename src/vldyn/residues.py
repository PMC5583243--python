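"""Residue identifiers with insertion codes ("27d") as ordered strings."""

from __future__ import annotations

__all__ = ["numeric_part", "sort_key", "order_residues"]


def numeric_part(residue_id: str) -> int:
    digits = "".join(ch for ch in str(residue_id) if ch.isdigit())
    if not digits:
        raise ValueError(f"residue id {residue_id!r} has no numeric part")
    return int(digits)


def sort_key(residue_id: str) -> tuple[int, str]:
    """Sequence order: number first, then insertion letter ('27' < '27d' < '28')."""
    rid = str(residue_id)
    letters = "".join(ch for ch in rid if ch.isalpha()).lower()
    return (numeric_part(rid), letters)


def order_residues(ids) -> list[str]:
    return sorted((str(r) for r in ids), key=sort_key)
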