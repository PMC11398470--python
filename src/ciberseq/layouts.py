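"""Read-architecture descriptions for long plasmid reads and short amplicon reads.

The exact flanking sequences are a property of the cloning vector and the
sequencing primers, so both layouts are user configuration (YAML) rather
than constants baked into the code.  The defaults below describe the
architecture used by the bundled simulator and serve as a template for
real libraries.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

_VALID_POLICIES = ("anchor_then_barcode", "barcode_then_anchor")


def _check_anchor(name: str, seq: str) -> str:
    seq = seq.upper()
    if len(seq) < 12:
        raise ValueError(f"anchor {name!r} must be at least 12 nt, got {len(seq)}")
    if set(seq) - set("ACGT"):
        raise ValueError(f"anchor {name!r} contains non-ACGT characters")
    return seq


@dataclass
class LongReadLayout:
    """Architecture of a long read covering one linearized library plasmid.

    Two barcodes (one per reporter channel) and the dual-sgRNA cassette are
    each bracketed by a pair of anchor sequences.  The cassette holds the
    two protospacers back to back, each ``guide_len`` nt.
    """

    anchor_up_red: str
    anchor_down_red: str
    anchor_up_ir: str
    anchor_down_ir: str
    anchor_guide_up: str
    anchor_guide_down: str
    barcode_len: int = 25
    guide_len: int = 20
    max_anchor_mismatch: int = 2

    def __post_init__(self) -> None:
        names = ("anchor_up_red", "anchor_down_red", "anchor_up_ir",
                 "anchor_down_ir", "anchor_guide_up", "anchor_guide_down")
        for name in names:
            setattr(self, name, _check_anchor(name, getattr(self, name)))
        anchors = [getattr(self, n) for n in names]
        if len(set(anchors)) != len(anchors):
            raise ValueError("anchors must be mutually distinct")
        if self.barcode_len <= 0:
            raise ValueError("barcode_len must be positive")
        if self.guide_len <= 0:
            raise ValueError("guide_len must be positive")
        if self.max_anchor_mismatch < 0:
            raise ValueError("max_anchor_mismatch must be >= 0")

    @property
    def anchors(self) -> dict[str, str]:
        return {
            "anchor_up_red": self.anchor_up_red,
            "anchor_down_red": self.anchor_down_red,
            "anchor_guide_up": self.anchor_guide_up,
            "anchor_guide_down": self.anchor_guide_down,
            "anchor_up_ir": self.anchor_up_ir,
            "anchor_down_ir": self.anchor_down_ir,
        }

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "LongReadLayout":
        return cls(**yaml.safe_load(Path(path).read_text()))


@dataclass
class ShortReadLayout:
    """Architecture of a short amplicon read carrying one UMI and one barcode.

    The UMI occupies the first ``umi_len`` bases (it is introduced by the
    reverse-transcription primer, so it sits at the 5' end of read 1).  The
    barcode is located relative to a fixed anchor sequence: either directly
    after it (``anchor_then_barcode``) or directly before it
    (``barcode_then_anchor``).
    """

    anchor: str
    barcode_len: int = 25
    umi_len: int = 10
    barcode_offset_policy: str = "anchor_then_barcode"
    max_anchor_mismatch: int = 2

    def __post_init__(self) -> None:
        self.anchor = _check_anchor("anchor", self.anchor)
        if self.barcode_len <= 0:
            raise ValueError("barcode_len must be positive")
        if self.umi_len <= 0:
            raise ValueError("umi_len must be positive")
        if self.barcode_offset_policy not in _VALID_POLICIES:
            raise ValueError(
                f"barcode_offset_policy must be one of {_VALID_POLICIES}")
        if self.max_anchor_mismatch < 0:
            raise ValueError("max_anchor_mismatch must be >= 0")

    @property
    def min_read_len(self) -> int:
        return self.umi_len + len(self.anchor) + self.barcode_len

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ShortReadLayout":
        return cls(**yaml.safe_load(Path(path).read_text()))


# Default architectures used by the simulator.  The anchor sequences are
# arbitrary fixed vector fragments; any real library must supply its own.
DEFAULT_LONG_LAYOUT = LongReadLayout(
    anchor_up_red="ACGGTCTCAGTCAGTGGACT",
    anchor_down_red="GATCCAGTTCGCTAACTGGA",
    anchor_guide_up="TTGCAGAGCCTAGACGTTCA",
    anchor_guide_down="CCATGAGTTACGGATCTGCA",
    anchor_up_ir="GGAACTCGATTCCGTAGTCA",
    anchor_down_ir="TACCGGATAGCTTGAACCTG",
)

DEFAULT_SHORT_LAYOUT = ShortReadLayout(
    anchor="GATCCAGTTCGCTAACTGGA",
)
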