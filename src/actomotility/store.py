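"""Keyword-annotated result store.

A store is a plain directory: each stored result is a JSON index document
(id, timestamp, stage, tags, config snapshot, seeds, payload paths and
hashes) next to its payload files (CSV/JSON).  Documents are retrieved by
conjunctive tag queries and can be reduced with custom functions, which
keeps large analysis campaigns navigable without a database.
"""

from __future__ import annotations

import hashlib
import json
import time
import uuid
from dataclasses import dataclass, field, asdict
from pathlib import Path

__all__ = ["ResultDocument", "ResultStore"]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class ResultDocument:
    """Index entry for one stored result."""

    id: str
    timestamp: float
    stage: str
    tags: dict
    config: dict
    seeds: dict
    payloads: dict  # name -> {"path": relative path, "sha256": hash}

    def payload_path(self, store: "ResultStore", name: str) -> Path:
        return store.root / self.payloads[name]["path"]


class ResultStore:
    """Directory-backed store of annotated analysis results."""

    def __init__(self, root):
        self.root = Path(root)
        self.root.mkdir(parents=True, exist_ok=True)

    # -- writing ----------------------------------------------------------
    def write(self, stage: str, tags: dict, payload_files: dict,
              config: dict | None = None,
              seeds: dict | None = None) -> ResultDocument:
        """Register payload files (already written inside the store root).

        ``payload_files`` maps payload names to paths; files outside the
        store root are rejected.  Tags must be non-empty.
        """
        if not tags:
            raise ValueError("tags must be non-empty")
        payloads = {}
        for name, p in payload_files.items():
            p = Path(p).resolve()
            rel = p.relative_to(self.root.resolve())
            payloads[name] = {"path": str(rel), "sha256": _sha256(p)}
        doc = ResultDocument(
            id=uuid.uuid4().hex[:12], timestamp=time.time(), stage=stage,
            tags=dict(tags), config=dict(config or {}),
            seeds=dict(seeds or {}), payloads=payloads)
        with open(self.root / f"{doc.id}.doc.json", "w") as fh:
            json.dump(asdict(doc), fh, indent=1)
        return doc

    def new_payload_dir(self, stage: str) -> Path:
        d = self.root / "payloads" / f"{stage}-{uuid.uuid4().hex[:8]}"
        d.mkdir(parents=True, exist_ok=True)
        return d

    # -- querying ---------------------------------------------------------
    def documents(self):
        for p in sorted(self.root.glob("*.doc.json")):
            with open(p) as fh:
                yield ResultDocument(**json.load(fh))

    def query(self, **tags) -> list[ResultDocument]:
        """Documents whose tags contain every given key/value pair."""
        out = []
        for doc in self.documents():
            if all(doc.tags.get(k) == v for k, v in tags.items()):
                out.append(doc)
        return out

    def apply(self, reducer, **tags):
        """Apply a reducer function to each matching document."""
        return [reducer(doc, self) for doc in self.query(**tags)]

    def verify(self, doc: ResultDocument) -> bool:
        """Round-trip integrity: payload hashes unchanged on disk."""
        return all(_sha256(self.root / p["path"]) == p["sha256"]
                   for p in doc.payloads.values())
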