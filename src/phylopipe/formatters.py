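"""Attribute formatters: number -> string, string -> number, value -> colour.

These are the declarative counterparts of the three formatter families
used by label and colour-aware plot stages:

* the string formatter rounds a number to significant or decimal
  digits (half-away-from-zero) and can drop values outside a threshold
  band — a node whose formatter returns nothing is simply not labelled;
* the number formatter parses decimal or scientific notation, failing
  softly to ``None``;
* the colour formatter accepts CSS-style strings (the 148 CSS named
  colours, ``#RGB``/``#RRGGBB``/``#RRGGBBAA``, ``rgb()``/``rgba()``)
  or maps a number onto a colour gradient.

Rendering uses plain decimal notation for magnitudes in
[1e-4, 1e7) and scientific notation outside that band.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import List, Optional, Tuple

from matplotlib.colors import CSS4_COLORS

__all__ = [
    "Colour",
    "Gradient",
    "FormatterSpec",
    "format_number",
    "parse_number",
    "parse_css_colour",
    "gradient_map",
    "apply_formatter",
    "ColourParseError",
]


@dataclass(frozen=True)
class Colour:
    """An 8-bit-per-channel RGBA colour."""

    r: int
    g: int
    b: int
    a: int = 255

    def __post_init__(self) -> None:
        for channel in (self.r, self.g, self.b, self.a):
            if not 0 <= channel <= 255:
                raise ValueError(f"colour channel {channel} out of [0, 255]")

    def css(self) -> str:
        return f"rgb({self.r},{self.g},{self.b})"

    @property
    def opacity(self) -> float:
        return self.a / 255.0

    def hex(self) -> str:
        return f"#{self.r:02X}{self.g:02X}{self.b:02X}" + (
            f"{self.a:02X}" if self.a != 255 else "")


@dataclass(frozen=True)
class Gradient:
    """Ordered colour stops at strictly increasing positions in [0, 1]."""

    stops: Tuple[Tuple[float, Colour], ...]

    def __post_init__(self) -> None:
        positions = [p for p, _ in self.stops]
        if len(positions) < 2 or positions[0] != 0.0 or positions[-1] != 1.0:
            raise ValueError("gradient stops must start at 0 and end at 1")
        if any(b <= a for a, b in zip(positions, positions[1:])):
            raise ValueError("gradient positions must be strictly increasing")


@dataclass
class FormatterSpec:
    """Declarative description of an attribute conversion.

    ``kind`` selects the family (``string_fmt``, ``number_fmt``,
    ``colour_fmt``); the remaining fields parameterise it. Specs are
    serialized inside pipeline documents.
    """

    kind: str = "string_fmt"
    digits: int = 3
    digit_mode: str = "significant"  # or "decimal"
    min_threshold: Optional[float] = None
    max_threshold: Optional[float] = None
    gradient: Optional[Gradient] = None
    domain: Optional[Tuple[float, float]] = None

    def __post_init__(self) -> None:
        if self.kind not in ("string_fmt", "number_fmt", "colour_fmt"):
            raise ValueError(f"unknown formatter kind {self.kind!r}")
        if self.digit_mode not in ("significant", "decimal"):
            raise ValueError(f"unknown digit mode {self.digit_mode!r}")
        if self.digits < 0:
            raise ValueError("digits must be >= 0")
        if (self.min_threshold is not None and self.max_threshold is not None
                and self.min_threshold > self.max_threshold):
            raise ValueError("min_threshold must be <= max_threshold")

    # -- serialization (pipeline documents) --------------------------
    def to_dict(self) -> dict:
        out: dict = {"kind": self.kind, "digits": self.digits,
                     "digit_mode": self.digit_mode}
        if self.min_threshold is not None:
            out["min_threshold"] = self.min_threshold
        if self.max_threshold is not None:
            out["max_threshold"] = self.max_threshold
        if self.gradient is not None:
            out["gradient"] = [[p, c.hex()] for p, c in self.gradient.stops]
        if self.domain is not None:
            out["domain"] = list(self.domain)
        return out

    @classmethod
    def from_dict(cls, data: dict) -> "FormatterSpec":
        gradient = None
        if "gradient" in data:
            gradient = Gradient(tuple(
                (float(p), parse_css_colour(c)) for p, c in data["gradient"]))
        domain = tuple(data["domain"]) if "domain" in data else None
        return cls(kind=data.get("kind", "string_fmt"),
                   digits=int(data.get("digits", 3)),
                   digit_mode=data.get("digit_mode", "significant"),
                   min_threshold=data.get("min_threshold"),
                   max_threshold=data.get("max_threshold"),
                   gradient=gradient, domain=domain)


class ColourParseError(ValueError):
    pass


# ---------------------------------------------------------------------------
# number -> string

_PLAIN_LOW = 1e-4
_PLAIN_HIGH = 1e7


def format_number(value: float, spec: FormatterSpec) -> Optional[str]:
    """Render a number per ``spec``; ``None`` means "skip this node".

    Values outside [min_threshold, max_threshold] (and NaN) are
    removed. Rounding is half-away-from-zero to ``spec.digits``
    significant or decimal digits; output is plain decimal for
    magnitudes in [1e-4, 1e7) and ``m e±x`` scientific notation
    otherwise.
    """
    value = float(value)
    if math.isnan(value):
        return None
    if spec.min_threshold is not None and value < spec.min_threshold:
        return None
    if spec.max_threshold is not None and value > spec.max_threshold:
        return None
    if math.isinf(value):
        return "inf" if value > 0 else "-inf"
    d = Decimal(repr(value))
    if spec.digit_mode == "decimal":
        q = d.quantize(Decimal(1).scaleb(-spec.digits), rounding=ROUND_HALF_UP)
    else:
        digits = max(1, spec.digits)
        if d == 0:
            q = Decimal(0).quantize(Decimal(1).scaleb(1 - digits))
        else:
            q = d.quantize(Decimal(1).scaleb(d.adjusted() - digits + 1),
                           rounding=ROUND_HALF_UP)
            if q.adjusted() != d.adjusted():  # e.g. 9.97 -> 10.0 at 2 sig
                q = q.quantize(Decimal(1).scaleb(q.adjusted() - digits + 1),
                               rounding=ROUND_HALF_UP)
    magnitude = abs(value)
    if magnitude == 0 or _PLAIN_LOW <= magnitude < _PLAIN_HIGH:
        return format(q, "f")
    exponent = q.adjusted()
    mantissa = q.scaleb(-exponent)
    sign = "+" if exponent >= 0 else "-"
    return f"{format(mantissa, 'f')}e{sign}{abs(exponent)}"


# ---------------------------------------------------------------------------
# string -> number

_FLOAT_RE = re.compile(
    r"[-+]?(\d+\.?\d*|\.\d+)([eE][-+]?\d+)?")


def parse_number(text: str) -> Optional[float]:
    """Parse decimal or scientific notation; ``None`` on failure."""
    if text is None:
        return None
    stripped = str(text).strip()
    if not _FLOAT_RE.fullmatch(stripped):
        return None
    return float(stripped)


# ---------------------------------------------------------------------------
# colours

_RGB_FUNC_RE = re.compile(
    r"rgba?\(\s*(\d+)\s*,\s*(\d+)\s*,\s*(\d+)\s*(?:,\s*([0-9.]+)\s*)?\)",
    re.IGNORECASE)


def parse_css_colour(text: str) -> Colour:
    """Parse a CSS-style colour string.

    Accepts the CSS named colours, ``#RGB``, ``#RRGGBB``, ``#RRGGBBAA``
    and the functional forms ``rgb(r, g, b)`` / ``rgba(r, g, b, a)``
    with a in [0, 1]. Case-insensitive.
    """
    token = text.strip()
    lower = token.lower()
    if lower in CSS4_COLORS:
        hex_code = CSS4_COLORS[lower]
        return Colour(int(hex_code[1:3], 16), int(hex_code[3:5], 16),
                      int(hex_code[5:7], 16))
    if token.startswith("#"):
        digits = token[1:]
        if not re.fullmatch(r"[0-9a-fA-F]+", digits or "x"):
            raise ColourParseError(f"invalid hex colour {text!r}")
        if len(digits) == 3:
            r, g, b = (int(ch * 2, 16) for ch in digits)
            return Colour(r, g, b)
        if len(digits) == 6:
            return Colour(int(digits[0:2], 16), int(digits[2:4], 16),
                          int(digits[4:6], 16))
        if len(digits) == 8:
            return Colour(int(digits[0:2], 16), int(digits[2:4], 16),
                          int(digits[4:6], 16), int(digits[6:8], 16))
        raise ColourParseError(f"invalid hex colour {text!r}")
    match = _RGB_FUNC_RE.fullmatch(token)
    if match:
        r, g, b = (int(match.group(i)) for i in (1, 2, 3))
        alpha = match.group(4)
        a = _round_half_away(float(alpha) * 255) if alpha is not None else 255
        return Colour(r, g, b, a)
    raise ColourParseError(f"unrecognised colour string {text!r}")


def _round_half_away(value: float) -> int:
    return int(math.floor(value + 0.5)) if value >= 0 else -int(
        math.floor(-value + 0.5))


def gradient_map(value: float, gradient: Gradient,
                 domain: Tuple[float, float]) -> Colour:
    """Map a number onto a colour gradient over ``domain``.

    The value is clamped into the domain, normalised to [0, 1], and the
    bracketing stops are interpolated per channel (half-away-from-zero
    rounding to integers).
    """
    lo, hi = domain
    if not lo < hi:
        raise ValueError("gradient domain must satisfy lo < hi")
    t = (float(value) - lo) / (hi - lo)
    t = min(1.0, max(0.0, t))
    stops = gradient.stops
    for (p0, c0), (p1, c1) in zip(stops, stops[1:]):
        if t <= p1:
            f = (t - p0) / (p1 - p0)
            return Colour(
                _round_half_away(c0.r + f * (c1.r - c0.r)),
                _round_half_away(c0.g + f * (c1.g - c0.g)),
                _round_half_away(c0.b + f * (c1.b - c0.b)),
                _round_half_away(c0.a + f * (c1.a - c0.a)))
    return stops[-1][1]


# ---------------------------------------------------------------------------
# dispatch used by label/colour-aware plot stages


def apply_formatter(value, spec: FormatterSpec):
    """Apply a formatter to an attribute value.

    string_fmt: numbers are formatted, text passes through unchanged.
    number_fmt: text is parsed, numbers pass through.
    colour_fmt: text is parsed as a CSS colour; numbers go through the
    gradient (which requires ``spec.gradient`` and ``spec.domain``).
    Returns ``None`` when the value should be skipped.
    """
    if value is None:
        return None
    if spec.kind == "string_fmt":
        if isinstance(value, (int, float)):
            return format_number(float(value), spec)
        return str(value)
    if spec.kind == "number_fmt":
        if isinstance(value, (int, float)):
            return float(value)
        return parse_number(str(value))
    if isinstance(value, (int, float)):
        if spec.gradient is None or spec.domain is None:
            raise ValueError("colour formatter for numbers needs a gradient "
                             "and a domain")
        return gradient_map(float(value), spec.gradient, spec.domain)
    return parse_css_colour(str(value))
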