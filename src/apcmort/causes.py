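"""ICD-9/ICD-10 external-cause codes -> (mechanism, intent) classification.

Three suicide mechanisms are tracked: hanging/strangulation/suffocation
(HSS), autointoxication (AUT) and firearm (FA), each with suicide,
accident, assault and undetermined-intent code ranges, plus the
mechanism-unspecific "sequelae of self-inflicted injury" codes.  The
packaged table mirrors the published mapping; intentional self-harm
ranges for HSS and AUT are not printed there and are carried as the
natural completion, flagged ``inferred`` in the provenance column.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources

import pandas as pd

MECHANISMS = ("HSS", "AUT", "FA")
INTENTS = ("suicide", "accident", "assault", "undetermined", "sequelae")

#: returned by :meth:`CauseMap.map_cause` for codes outside every range
NOT_IN_SCOPE = ("none", "not_in_scope")

_ICD10_RE = re.compile(r"^([A-Z])(\d{2})(\d{1,2}|\.\d{1,2})?$")
_ICD9_RE = re.compile(r"^E(\d{3})(\d|\.\d)?$")


class MalformedCodeError(ValueError):
    """Raised for strings that are not syntactically valid ICD codes."""


def _root(code: str, icd_revision: int) -> tuple[str, int]:
    """Normalize a code to its 3-character category root.

    Returns (letter, number) for ICD-10 ("X720", "X72.0", "X72" -> ("X", 72))
    and ("E", number) for ICD-9 E-codes ("E9550" -> ("E", 955)).  Trailing
    subdivision digits, with or without a decimal point, are discarded.
    """
    code = str(code).strip().upper()
    if icd_revision == 10:
        m = _ICD10_RE.match(code)
        if not m:
            raise MalformedCodeError(f"malformed ICD-10 code: {code!r}")
        return m.group(1), int(m.group(2))
    if icd_revision == 9:
        m = _ICD9_RE.match(code)
        if not m:
            raise MalformedCodeError(f"malformed ICD-9 E-code: {code!r}")
        return "E", int(m.group(1))
    raise ValueError(f"unsupported ICD revision: {icd_revision!r}")


@dataclass(frozen=True)
class CodeRange:
    mechanism: str
    intent: str
    icd_revision: int
    start: str
    end: str
    provenance: str = "printed"

    def contains(self, code: str) -> bool:
        letter, num = _root(code, self.icd_revision)
        lo_letter, lo_num = _root(self.start, self.icd_revision)
        hi_letter, hi_num = _root(self.end, self.icd_revision)
        if lo_letter != hi_letter:
            # ranges never span ICD-10 chapters in this table
            raise ValueError(f"range {self.start}-{self.end} spans letters")
        return letter == lo_letter and lo_num <= num <= hi_num


class CauseMap:
    """Inclusive code-range table mapping codes to (mechanism, intent)."""

    def __init__(self, ranges: list[CodeRange]):
        self.ranges = list(ranges)
        self._check_overlaps()

    def _check_overlaps(self) -> None:
        # overlapping ranges within one revision would make map_cause ambiguous
        for rev in (9, 10):
            spans = []
            for r in self.ranges:
                if r.icd_revision != rev:
                    continue
                lo = _root(r.start, rev)
                hi = _root(r.end, rev)
                for l2, h2, other in spans:
                    if lo[0] == l2[0] and not (hi[1] < l2[1] or lo[1] > h2[1]):
                        raise ValueError(
                            f"overlapping ICD-{rev} ranges: "
                            f"{r.start}-{r.end} vs {other.start}-{other.end}")
                spans.append((lo, hi, r))

    @classmethod
    def load_packaged(cls) -> "CauseMap":
        """Load the versioned mapping shipped with the package."""
        with resources.files("apcmort.data").joinpath("cause_map.csv").open() as fh:
            df = pd.read_csv(fh, comment="#")
        return cls.from_frame(df)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CauseMap":
        ranges = [
            CodeRange(r.mechanism, r.intent, int(r.icd_revision),
                      str(r.code_start), str(r.code_end),
                      getattr(r, "provenance", "printed"))
            for r in df.itertuples()
        ]
        return cls(ranges)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "mechanism": r.mechanism, "intent": r.intent,
            "icd_revision": r.icd_revision, "code_start": r.start,
            "code_end": r.end, "provenance": r.provenance,
        } for r in self.ranges])

    def map_cause(self, cause_code: str, icd_revision: int) -> tuple[str, str]:
        """Classify one code; codes outside every range return NOT_IN_SCOPE.

        Malformed code strings raise :class:`MalformedCodeError` naming the
        code.  ICD-10 codes that are not E-coded under ICD-9 conventions
        (and vice versa) are likewise rejected.
        """
        _root(cause_code, icd_revision)  # validate syntax up front
        for r in self.ranges:
            if r.icd_revision == icd_revision and r.contains(cause_code):
                return r.mechanism, r.intent
        return NOT_IN_SCOPE

    def suicide_code(self, mechanism: str, icd_revision: int = 10) -> str:
        """A representative suicide code for a mechanism (range start)."""
        return self.code_for(mechanism, "suicide", icd_revision)

    def code_for(self, mechanism: str, intent: str, icd_revision: int = 10) -> str:
        for r in self.ranges:
            if (r.mechanism == mechanism and r.intent == intent
                    and r.icd_revision == icd_revision):
                return r.start
        raise KeyError(f"no range for {mechanism}/{intent}/ICD-{icd_revision}")


def map_cause(cause_code: str, icd_revision: int,
              cause_map: CauseMap | None = None) -> tuple[str, str]:
    """Module-level convenience using the packaged mapping."""
    cm = cause_map or _packaged()
    return cm.map_cause(cause_code, icd_revision)


_PACKAGED: CauseMap | None = None


def _packaged() -> CauseMap:
    global _PACKAGED
    if _PACKAGED is None:
        _PACKAGED = CauseMap.load_packaged()
    return _PACKAGED
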