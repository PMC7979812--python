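"""Multi-line text layouts: per-word bounding boxes on a pixel display.

A :class:`TextLayout` is the geometric substrate of every word-based
analysis stage — it plays the role of the word/interest-area description
a display program would export alongside an eye-movement recording.
Coordinates are 0-based pixels, origin top-left, y increasing downward.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable


@dataclass(frozen=True)
class WordBox:
    """Axis-aligned bounding box of one word.

    ``word_index`` counts words in reading order across the whole text;
    ``line_index`` counts lines from the top.  ``char_count`` is the number
    of characters the box spans (>= 1).
    """

    word_index: int
    line_index: int
    x0: float
    y0: float
    x1: float
    y1: float
    char_count: int

    def __post_init__(self) -> None:
        if not (self.x0 < self.x1 and self.y0 < self.y1):
            raise ValueError(f"degenerate word box {self}")
        if self.char_count < 1:
            raise ValueError("char_count must be >= 1")

    @property
    def center(self) -> tuple[float, float]:
        return (0.5 * (self.x0 + self.x1), 0.5 * (self.y0 + self.y1))

    @property
    def width(self) -> float:
        return self.x1 - self.x0


@dataclass
class TextLayout:
    """Ordered word boxes of a left-aligned multi-line text."""

    words: list[WordBox]
    display_width: float = 1024.0
    display_height: float = 768.0
    text_id: str = ""

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants -----------------------------------------------------
    def validate(self) -> None:
        prev: WordBox | None = None
        for i, w in enumerate(self.words):
            if w.word_index != i:
                raise ValueError("word indices must be 0..n-1 in reading order")
            if not (0 <= w.x0 and w.x1 <= self.display_width
                    and 0 <= w.y0 and w.y1 <= self.display_height):
                raise ValueError(f"word {i} outside display bounds")
            if prev is not None:
                if w.line_index < prev.line_index:
                    raise ValueError("line indices must be non-decreasing")
                if w.line_index == prev.line_index and w.x0 < prev.x1:
                    raise ValueError(
                        f"words {prev.word_index},{w.word_index} overlap on line"
                    )
            prev = w

    # -- accessors ------------------------------------------------------
    @property
    def n_words(self) -> int:
        return len(self.words)

    @property
    def line_count(self) -> int:
        return 0 if not self.words else self.words[-1].line_index + 1

    def words_on_line(self, line_index: int) -> list[WordBox]:
        return [w for w in self.words if w.line_index == line_index]

    def line_of_word(self, word_index: int) -> int:
        return self.words[word_index].line_index

    def line_word_span(self, line_index: int) -> tuple[int, int]:
        """(first, last) global word index on a line."""
        ws = self.words_on_line(line_index)
        if not ws:
            raise ValueError(f"no words on line {line_index}")
        return ws[0].word_index, ws[-1].word_index

    def within_line_position(self, word_index: int) -> tuple[int, int]:
        """(index from line start, index from line end) of a word, 0-based."""
        w = self.words[word_index]
        first, last = self.line_word_span(w.line_index)
        return word_index - first, last - word_index

    # -- serialization --------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        payload = {
            "text_id": self.text_id,
            "display_width": self.display_width,
            "display_height": self.display_height,
            "words": [
                {
                    "word": w.word_index,
                    "line": w.line_index,
                    "bbox": [w.x0, w.y0, w.x1, w.y1],
                    "chars": w.char_count,
                }
                for w in self.words
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "TextLayout":
        payload = json.loads(Path(path).read_text())
        words = [
            WordBox(d["word"], d["line"], *d["bbox"], d["chars"])
            for d in payload["words"]
        ]
        return cls(
            words,
            display_width=payload["display_width"],
            display_height=payload["display_height"],
            text_id=payload.get("text_id", ""),
        )
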