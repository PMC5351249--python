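"""Composite Autonomic Scoring System (CASS) summation.

The CASS grades autonomic deficits on a 10-point scale summing three
subscales: sudomotor (0-3), cardiovagal (0-3) and adrenergic (0-4).
A total of zero means no autonomic dysfunction; any total of 1-10 is
dichotomized as autonomic dysfunction.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ValidationError

SUBSCALE_MAX = {"sudomotor": 3, "cardiovagal": 3, "adrenergic": 4}


@dataclass(frozen=True)
class CASSResult:
    sudomotor: int
    cardiovagal: int
    adrenergic: int
    total: int
    dysfunction: bool
    limb_positive: tuple[bool, bool, bool]  # sudomotor, cardiovagal, adrenergic


def _check(name: str, value) -> int:
    if isinstance(value, bool) or not isinstance(value, (int,)):
        # floats representing integers are accepted; half-points are not
        if isinstance(value, float) and value == int(value) and not isinstance(value, bool):
            value = int(value)
        else:
            raise ValidationError(f"{name} subscore must be an integer, got {value!r}")
    cap = SUBSCALE_MAX[name]
    if not 0 <= value <= cap:
        raise ValidationError(f"{name} subscore {value} outside 0..{cap}")
    return value


def score_cass(sudomotor: int, cardiovagal: int, adrenergic: int) -> CASSResult:
    """Sum the three subscale scores and apply the dysfunction dichotomy.

    Returns the total (0-10), ``dysfunction`` (total >= 1) and per-limb
    positivity flags (subscore >= 1).  Out-of-range or non-integer
    subscores raise :class:`~abpauto.errors.ValidationError` naming the
    subscale.
    """
    s = _check("sudomotor", sudomotor)
    c = _check("cardiovagal", cardiovagal)
    a = _check("adrenergic", adrenergic)
    total = s + c + a
    return CASSResult(
        sudomotor=s,
        cardiovagal=c,
        adrenergic=a,
        total=total,
        dysfunction=total >= 1,
        limb_positive=(s >= 1, c >= 1, a >= 1),
    )
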