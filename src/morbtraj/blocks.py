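"""ICD-10 diagnosis blocks: contiguous ranges of level-3 codes.

The WHO groups the 1074 level-3 codes A00--N99 (somatic chapters I--XIV)
into 131 blocks such as I10--I15 "Hypertensive diseases".  A packaged copy
of that table ships with the package; small synthetic tables can be built
for tests and toy examples.  Codes are compared lexicographically, which is
correct for the fixed letter+2-digit format.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .errors import BlockTableParseError, ValidationError

_CODE_RE = re.compile(r"^[A-Z][0-9]{2}")
_LEVEL3_RE = re.compile(r"^[A-Z][0-9]{2}$")

#: default washout exclusion range (the somatic chapters)
SOMATIC_RANGE = ("A00", "N99")


def normalise_code(code: str) -> str:
    """Truncate an ICD-10 code to level 3 (letter + two digits).

    Codes with a 4th character ("E11.9", "I109") are truncated; anything
    not starting with that pattern raises :class:`ValidationError`.
    """
    if not isinstance(code, str) or not _CODE_RE.match(code):
        raise ValidationError(f"not an ICD-10 code: {code!r}")
    return code[:3]


@dataclass(frozen=True)
class BlockTable:
    """Disjoint, ordered ranges of level-3 ICD-10 codes.

    Attributes
    ----------
    frame : pandas.DataFrame
        Columns ``block_id, chapter, first_code, last_code, label``,
        sorted by ``first_code`` with ``block_id`` equal to the row index.
    """

    frame: pd.DataFrame

    def __post_init__(self):
        f = self.frame
        required = {"block_id", "chapter", "first_code", "last_code", "label"}
        missing = required - set(f.columns)
        if missing:
            raise BlockTableParseError(0, f"missing columns {sorted(missing)}")
        for i, row in enumerate(f.itertuples(index=False), start=2):
            for c in (row.first_code, row.last_code):
                if not _LEVEL3_RE.match(str(c)):
                    raise BlockTableParseError(i, f"not a level-3 code: {c!r}")
            if row.last_code < row.first_code:
                raise BlockTableParseError(i, f"inverted range {row.first_code}-{row.last_code}")
        s = f.sort_values("first_code").reset_index(drop=True)
        prev_last, prev_line = None, None
        for i, row in enumerate(s.itertuples(index=False)):
            if prev_last is not None and row.first_code <= prev_last:
                raise BlockTableParseError(
                    i + 2, f"range {row.first_code}-{row.last_code} overlaps previous (ends {prev_last})"
                )
            prev_last = row.last_code
        object.__setattr__(self, "frame", s.assign(block_id=s["block_id"].astype(int)))

    @property
    def n_blocks(self) -> int:
        return len(self.frame)

    def label(self, block_id: int) -> str:
        row = self.frame.loc[self.frame["block_id"] == block_id].iloc[0]
        return f"{row.first_code}-{row.last_code}"

    def description(self, block_id: int) -> str:
        return str(self.frame.loc[self.frame["block_id"] == block_id, "label"].iloc[0])

    # -- lookup ---------------------------------------------------------

    def map_code(self, code: str) -> int | None:
        """Return the block_id containing ``code`` or None if outside all ranges."""
        c = normalise_code(code)
        firsts = self.frame["first_code"].to_numpy()
        idx = int(np.searchsorted(firsts, c, side="right")) - 1
        if idx < 0:
            return None
        row = self.frame.iloc[idx]
        if c <= row["last_code"]:
            return int(row["block_id"])
        return None

    def map_codes(self, codes: pd.Series) -> pd.Series:
        """Vectorised :meth:`map_code`; invalid codes raise, misses become NaN."""
        c = codes.astype(str).str.slice(0, 3)
        bad = ~c.str.match(_CODE_RE)
        if bad.any():
            raise ValidationError(f"not an ICD-10 code: {codes[bad].iloc[0]!r}")
        firsts = self.frame["first_code"].to_numpy()
        lasts = self.frame["last_code"].to_numpy()
        ids = self.frame["block_id"].to_numpy()
        pos = np.searchsorted(firsts, c.to_numpy(), side="right") - 1
        ok = pos >= 0
        pos_c = np.clip(pos, 0, None)
        ok &= c.to_numpy() <= lasts[pos_c]
        out = np.where(ok, ids[pos_c], -1)
        return pd.Series(out, index=codes.index).replace(-1, np.nan)

    def random_code(self, block_id: int, rng: np.random.Generator) -> str:
        """A uniformly drawn level-3 code within the block's range."""
        row = self.frame.loc[self.frame["block_id"] == block_id].iloc[0]
        letter = row["first_code"][0]
        lo, hi = int(row["first_code"][1:]), int(row["last_code"][1:])
        return f"{letter}{rng.integers(lo, hi + 1):02d}"

    # -- constructors ---------------------------------------------------

    @classmethod
    def from_csv(cls, path) -> "BlockTable":
        try:
            frame = pd.read_csv(path, dtype=str)
        except Exception as exc:  # pragma: no cover - pandas error text varies
            raise BlockTableParseError(0, str(exc)) from exc
        frame["block_id"] = range(len(frame)) if "block_id" not in frame else frame["block_id"]
        return cls(frame)

    @classmethod
    def packaged_who(cls) -> "BlockTable":
        """The WHO A00--N99 grouping into 131 blocks shipped with the package."""
        with resources.files("morbtraj.data").joinpath("icd10_blocks_a00_n99.csv").open() as fh:
            return cls.from_csv(fh)

    @classmethod
    def synthetic(cls, n_blocks: int) -> "BlockTable":
        """``n_blocks`` disjoint toy ranges spread over letters A..N.

        Each letter hosts up to 10 blocks of 10 codes each (X00-X09, ...),
        enough for 140 blocks; used when no WHO file is wanted.
        """
        if n_blocks < 1:
            raise BlockTableParseError(0, "n_blocks must be >= 1")
        if n_blocks > 140:
            raise BlockTableParseError(0, "synthetic tables support at most 140 blocks")
        rows = []
        letters = "ABCDEFGHIJKLMN"
        for b in range(n_blocks):
            letter = letters[b // 10]
            lo = (b % 10) * 10
            rows.append(
                {
                    "block_id": b,
                    "chapter": letter,
                    "first_code": f"{letter}{lo:02d}",
                    "last_code": f"{letter}{lo + 9:02d}",
                    "label": f"Synthetic block {b}",
                }
            )
        return cls(pd.DataFrame(rows))


def default_block_table(n_blocks: int = 131) -> BlockTable:
    """The packaged WHO table when ``n_blocks`` matches it, else a synthetic one."""
    if n_blocks == 131:
        return BlockTable.packaged_who()
    return BlockTable.synthetic(n_blocks)


def in_code_range(codes: pd.Series, lo: str = SOMATIC_RANGE[0], hi: str = SOMATIC_RANGE[1]) -> pd.Series:
    """Boolean mask: level-3 truncation of each code falls in [lo, hi]."""
    c = codes.astype(str).str.slice(0, 3)
    return (c >= lo) & (c <= hi)
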