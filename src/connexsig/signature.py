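"""Query gene-signature construction from a filtered DEG table.

A signature is the pair of ordered tag lists fed to a connectivity query: the
most up-regulated genes (descending logFC) and the most down-regulated genes
(ascending logFC), at most 150 per direction and 300 in total by convention.
An optional allowed-gene list (the BING-style query space) can be applied
either after top-k selection (default, so signatures may end up shorter) or
before it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .errors import FormatError, ValidationError


@dataclass(frozen=True)
class GeneSignature:
    signature_id: str
    up_tags: tuple[str, ...] = ()
    down_tags: tuple[str, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "up_tags", tuple(self.up_tags))
        object.__setattr__(self, "down_tags", tuple(self.down_tags))
        if len(set(self.up_tags)) != len(self.up_tags):
            raise ValidationError("duplicate up tags")
        if len(set(self.down_tags)) != len(self.down_tags):
            raise ValidationError("duplicate down tags")
        overlap = set(self.up_tags) & set(self.down_tags)
        if overlap:
            raise ValidationError(f"tags in both directions: {sorted(overlap)[:5]}")

    def __len__(self) -> int:
        return len(self.up_tags) + len(self.down_tags)


@dataclass
class SignatureConfig:
    max_per_direction: int = 150
    max_total: int = 300
    allowed_genes: frozenset[str] | None = None
    allowed_filter_order: str = "after_selection"

    def __post_init__(self):
        if self.allowed_genes is not None:
            self.allowed_genes = frozenset(self.allowed_genes)
        if self.allowed_filter_order not in {"after_selection", "before_selection"}:
            raise ValidationError(
                f"unknown allowed_filter_order {self.allowed_filter_order!r}"
            )
        if self.max_per_direction < 0 or self.max_total < 0:
            raise ValidationError("caps must be non-negative")


def build_signature(
    degs: pd.DataFrame, cfg: SignatureConfig | None = None, signature_id: str = "query"
) -> GeneSignature:
    """Select up/down tags from a (pre-filtered) DEG table.

    Up tags: top ``max_per_direction`` genes with logFC > 0 in descending logFC
    order; down tags: most negative logFC first. Genes with logFC exactly 0
    belong to neither direction. Ties are broken by ascending q then gene_id.
    The allowed-gene filter is applied before or after the top-k cut per
    ``allowed_filter_order``.
    """
    cfg = cfg or SignatureConfig()
    if degs.empty:
        return GeneSignature(signature_id)
    cols = ["logFC", "q", "gene_id"] if "q" in degs.columns else ["logFC", "gene_id"]
    up = degs[degs["logFC"] > 0].sort_values(
        cols, ascending=[False] + [True] * (len(cols) - 1), kind="stable"
    )
    down = degs[degs["logFC"] < 0].sort_values(
        cols, ascending=[True] * len(cols), kind="stable"
    )
    up_tags = list(up["gene_id"].astype(str))
    down_tags = list(down["gene_id"].astype(str))

    def allowed(tags: list[str]) -> list[str]:
        if cfg.allowed_genes is None:
            return tags
        return [t for t in tags if t in cfg.allowed_genes]

    if cfg.allowed_filter_order == "before_selection":
        up_tags, down_tags = allowed(up_tags), allowed(down_tags)
    up_tags = up_tags[: cfg.max_per_direction]
    down_tags = down_tags[: cfg.max_per_direction]
    if cfg.allowed_filter_order == "after_selection":
        up_tags, down_tags = allowed(up_tags), allowed(down_tags)
    # unreachable at the 150/150/300 defaults; trim the longer list from its tail
    while len(up_tags) + len(down_tags) > cfg.max_total:
        if len(down_tags) >= len(up_tags):
            down_tags.pop()
        else:
            up_tags.pop()
    return GeneSignature(signature_id, tuple(up_tags), tuple(down_tags))


_HEADER = "SIGNATURE"


def write_signature(sig: GeneSignature, path) -> Path:
    """Two-block text format: a header line, then UP and DOWN tag blocks."""
    path = Path(path)
    lines = [f"{_HEADER}\t{sig.signature_id}", "UP", *sig.up_tags, "DOWN", *sig.down_tags]
    path.write_text("\n".join(lines) + "\n")
    return path


def read_signature(path) -> GeneSignature:
    lines = Path(path).read_text().splitlines()
    if not lines or not lines[0].startswith(_HEADER + "\t"):
        raise FormatError(f"line 1: expected '{_HEADER}<TAB>id' header")
    signature_id = lines[0].split("\t", 1)[1]
    if len(lines) < 2 or lines[1] != "UP":
        raise FormatError("line 2: expected 'UP' block header")
    try:
        down_at = lines.index("DOWN", 1)
    except ValueError as exc:
        raise FormatError("missing 'DOWN' block header") from exc
    up = tuple(t for t in lines[2:down_at] if t)
    down = tuple(t for t in lines[down_at + 1 :] if t)
    return GeneSignature(signature_id, up, down)
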