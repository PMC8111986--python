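"""Gene-set collections and GMT input/output."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path


class GmtParseError(ValueError):
    """Raised for a malformed GMT line; message names the line number."""


@dataclass
class GeneSetCollection:
    """Named gene sets with optional free-text descriptions.

    Set names are unique; genes within a set are deduplicated preserving
    first-occurrence order.
    """

    sets: dict[str, list[str]] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def add(self, name: str, genes: list[str], description: str = "") -> None:
        if name in self.sets:
            raise ValueError(f"duplicate gene-set name: {name!r}")
        deduped = list(dict.fromkeys(genes))
        self.sets[name] = deduped
        self.descriptions[name] = description

    def subset(self, names: list[str]) -> "GeneSetCollection":
        out = GeneSetCollection()
        for n in names:
            out.add(n, self.sets[n], self.descriptions.get(n, ""))
        return out


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a tab-separated GMT file: ``name<TAB>description<TAB>gene...``.

    Each line needs at least three fields (name, description, one gene).
    Duplicate genes within a set are collapsed; a repeated set name is an
    error. Empty files yield an empty collection.
    """
    coll = GeneSetCollection()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GmtParseError(
                    f"{path}: line {lineno}: expected >= 3 tab-separated "
                    f"fields, got {len(fields)}"
                )
            name, desc, genes = fields[0], fields[1], fields[2:]
            genes = [g for g in genes if g]
            try:
                coll.add(name, genes, desc)
            except ValueError as exc:
                raise GmtParseError(f"{path}: line {lineno}: {exc}") from exc
    return coll


def write_gmt(coll: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in coll.sets.items():
            desc = coll.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *genes]) + "\n")
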