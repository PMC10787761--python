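"""Lightweight per-stage diagnostics: named counters plus free-text notes.

Every lossy decision in the pipeline (dropped reaction, skipped xref,
unmapped entity, removed non-human edge) increments a counter here so that
input/output bookkeeping can be reconciled after a run.
"""

from __future__ import annotations

from collections import Counter


class Diagnostics:
    """Mutable tally of counts and messages for one pipeline stage or run."""

    def __init__(self) -> None:
        self.counts: Counter[str] = Counter()
        self.messages: list[str] = []

    def count(self, key: str, n: int = 1) -> None:
        self.counts[key] += n

    def note(self, message: str) -> None:
        self.messages.append(message)

    def merge(self, other: "Diagnostics") -> None:
        self.counts.update(other.counts)
        self.messages.extend(other.messages)

    def as_dict(self) -> dict:
        return {"counts": dict(sorted(self.counts.items())), "messages": list(self.messages)}

    def __getitem__(self, key: str) -> int:
        return self.counts[key]

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Diagnostics(counts={dict(self.counts)!r}, messages={len(self.messages)})"
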