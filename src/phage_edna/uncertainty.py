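"""Standard uncertainties with first-order (delta-method) propagation.

A :class:`UValue` pairs a point estimate with a standard uncertainty and
propagates the uncertainty through arithmetic under the usual first-order
assumptions: independent errors, small relative uncertainties.  The module
also implements the compact parentheses notation used to report measured
quantities — ``"0.5(1)"`` means 0.5 with a standard uncertainty of 0.1
applied to the last significant digit, ``"1.3(4)e10"`` means 1.3e10 with
an uncertainty of 0.4e10.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass

__all__ = ["UValue", "parse_uvalue", "format_uvalue", "UValueParseError"]


class UValueParseError(ValueError):
    """Raised when a parentheses-notation string cannot be parsed."""


_UVALUE_RE = re.compile(
    r"""^\s*
        (?P<sign>[+-]?)
        (?P<int>\d+)
        (?:\.(?P<frac>\d+))?
        \((?P<paren>\d+)\)
        (?:[eE](?P<exp>[+-]?\d+))?
        \s*$""",
    re.VERBOSE,
)


@dataclass(frozen=True)
class UValue:
    """A value with a standard uncertainty (one standard deviation).

    Units are carried by context, not by the object; operations that mix
    units are the caller's responsibility.
    """

    value: float
    sd: float = 0.0

    def __post_init__(self) -> None:
        if not math.isfinite(self.value):
            raise ValueError(f"value must be finite, got {self.value}")
        if not (self.sd >= 0.0):
            raise ValueError(f"sd must be >= 0, got {self.sd}")

    # -- arithmetic with independent-error propagation ------------------

    def __add__(self, other: "UValue | float") -> "UValue":
        other = _as_uvalue(other)
        return UValue(self.value + other.value, math.hypot(self.sd, other.sd))

    __radd__ = __add__

    def __sub__(self, other: "UValue | float") -> "UValue":
        other = _as_uvalue(other)
        return UValue(self.value - other.value, math.hypot(self.sd, other.sd))

    def __rsub__(self, other: "UValue | float") -> "UValue":
        return _as_uvalue(other) - self

    def __mul__(self, other: "UValue | float") -> "UValue":
        if not isinstance(other, UValue):
            return UValue(self.value * other, self.sd * abs(other))
        value = self.value * other.value
        sd = math.hypot(other.value * self.sd, self.value * other.sd)
        return UValue(value, sd)

    __rmul__ = __mul__

    def __truediv__(self, other: "UValue | float") -> "UValue":
        if not isinstance(other, UValue):
            if other == 0:
                raise ZeroDivisionError("division of UValue by zero")
            return UValue(self.value / other, self.sd / abs(other))
        if other.value == 0:
            raise ZeroDivisionError("division of UValue by zero-valued UValue")
        value = self.value / other.value
        if self.value != 0:
            sd = abs(value) * math.hypot(
                self.sd / self.value, other.sd / other.value
            )
        else:
            sd = self.sd / abs(other.value)
        return UValue(value, sd)

    def __neg__(self) -> "UValue":
        return UValue(-self.value, self.sd)

    def scale(self, k: float) -> "UValue":
        """Exact scaling: both value and sd multiplied by ``k``."""
        return UValue(self.value * k, self.sd * abs(k))

    # -- notation -------------------------------------------------------

    def __format__(self, spec: str) -> str:
        if spec:
            return format(self.value, spec)
        return format_uvalue(self)

    def __str__(self) -> str:
        return format_uvalue(self)


def _as_uvalue(x: "UValue | float") -> UValue:
    return x if isinstance(x, UValue) else UValue(float(x), 0.0)


def parse_uvalue(text: str) -> UValue:
    """Parse parentheses notation into a :class:`UValue`.

    The parenthesized digits map onto the last significant digit(s) of the
    value: ``"0.14(2)"`` -> 0.14 +/- 0.02, ``"7(2)e7"`` -> 7e7 +/- 2e7,
    ``"0.5(12)"`` -> 0.5 +/- 1.2 (multi-digit uncertainties allowed).
    """
    m = _UVALUE_RE.match(text)
    if m is None:
        raise UValueParseError(
            f"malformed uncertainty string {text!r}: expected "
            "'<digits>[.<digits>](<digits>)[e<exp>]'"
        )
    frac = m.group("frac") or ""
    exp = int(m.group("exp") or 0)
    sign = -1.0 if m.group("sign") == "-" else 1.0
    mantissa = float(f"{m.group('int')}.{frac or '0'}")
    value = sign * mantissa * 10.0**exp
    sd = int(m.group("paren")) * 10.0 ** (exp - len(frac))
    return UValue(value, sd)


def format_uvalue(u: UValue, sig_digits: int = 1) -> str:
    """Format a :class:`UValue` in parentheses notation.

    The uncertainty is rounded to ``sig_digits`` significant digits
    (default 1) and the value is rounded to the same decimal place.
    Scientific notation is used when the value's decade is >= 5 or <= -5,
    matching how copy numbers such as ``1.3(4)e10`` are reported.
    """
    if sig_digits < 1:
        raise ValueError("sig_digits must be >= 1")
    v, s = u.value, u.sd
    if s == 0.0:
        return repr(v)
    # Round sd to sig_digits significant digits; rounding can carry
    # (e.g. 0.096 -> 0.10 at one digit means digits=1, place shifts).
    e_sd = math.floor(math.log10(s))
    place = e_sd - (sig_digits - 1)
    digits = round(s / 10.0**place)
    if digits >= 10**sig_digits:
        e_sd += 1
        place += 1
        digits = round(s / 10.0**place)

    # Decide notation from the *rounded* value so a rounding carry across
    # a decade (e.g. 99999.99 -> 100000.0) cannot break round-tripping.
    v_r = round(v / 10.0**place) * 10.0**place
    e_val = math.floor(math.log10(abs(v_r))) if v_r != 0 else 0
    scientific = v_r != 0 and (e_val >= 5 or e_val <= -5)
    if scientific:
        mant = v_r / 10.0**e_val
        decimals = max(0, e_val - place)
        return f"{mant:.{decimals}f}({digits})e{e_val}"
    if place > 0:
        # Uncertainty larger than the units digit: spell it out in full.
        v_r = round(v / 10.0**place) * 10**place
        return f"{v_r:.0f}({digits * 10 ** place:d})"
    decimals = -place
    return f"{v:.{decimals}f}({digits})"
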