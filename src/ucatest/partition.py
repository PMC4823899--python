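"""Grouping of sequence identifiers into putative independent-origin groups."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Tuple

import yaml


@dataclass(frozen=True)
class Partition:
    """Disjoint groups of sequence identifiers.

    A single group is the degenerate (common-ancestry) partition; two or
    more groups encode an independent-origins hypothesis.
    """

    groups: Tuple[Tuple[str, Tuple[str, ...]], ...]

    @classmethod
    def from_dict(cls, mapping: Dict[str, Iterable[str]]) -> "Partition":
        return cls(tuple((name, tuple(ids)) for name, ids in mapping.items()))

    @classmethod
    def from_yaml(cls, path) -> "Partition":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise ValueError("groups file must map group names to identifier lists")
        return cls.from_dict(data)

    def __post_init__(self):
        seen = set()
        for name, ids in self.groups:
            if not ids:
                raise ValueError(f"group {name!r} is empty")
            for i in ids:
                if i in seen:
                    raise ValueError(f"identifier {i!r} appears in two groups")
                seen.add(i)

    @property
    def names(self) -> List[str]:
        return [n for n, _ in self.groups]

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    def members(self, name: str) -> List[str]:
        for n, ids in self.groups:
            if n == name:
                return list(ids)
        raise KeyError(name)

    def all_ids(self) -> List[str]:
        return [i for _, ids in self.groups for i in ids]

    def group_of(self, ident: str) -> str:
        for n, ids in self.groups:
            if ident in ids:
                return n
        raise KeyError(ident)

    def validate_against(self, idents: Sequence[str]) -> None:
        """Require the groups to exactly cover the given identifiers."""
        if set(self.all_ids()) != set(idents):
            raise ValueError("partition does not cover the sequence identifiers")


def as_partition(obj) -> Partition:
    if isinstance(obj, Partition):
        return obj
    if isinstance(obj, dict):
        return Partition.from_dict(obj)
    raise TypeError("expected a Partition or a {group: [ids]} mapping")
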