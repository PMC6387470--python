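"""Shared machinery for fit results: parameter tables and text summaries."""

from __future__ import annotations

import math
from typing import Mapping


def format_sig(x: float, sig: int = 3) -> str:
    """Format a number to ``sig`` significant figures (plain or exponent)."""
    if x == 0 or not math.isfinite(x):
        return f"{x:g}"
    return f"{x:.{sig}g}"


def summary_table(
    title: str,
    params: Mapping[str, float],
    bse: Mapping[str, float] | None = None,
    extra: Mapping[str, object] | None = None,
    sig: int = 4,
) -> str:
    """Render a statsmodels-flavoured fixed-width text summary."""
    lines = [title, "=" * max(len(title), 44)]
    name_w = max([len(k) for k in params] + [9])
    header = f"{'parameter':<{name_w}}  {'estimate':>12}  {'std err':>12}"
    lines.append(header)
    lines.append("-" * len(header))
    for name, value in params.items():
        se = (bse or {}).get(name, float("nan"))
        se_txt = format_sig(se, sig) if math.isfinite(se) else "--"
        lines.append(f"{name:<{name_w}}  {format_sig(value, sig):>12}  {se_txt:>12}")
    if extra:
        lines.append("-" * len(header))
        for name, value in extra.items():
            if isinstance(value, float):
                value = format_sig(value, sig)
            lines.append(f"{name:<{name_w}}  {value}")
    lines.append("=" * max(len(title), 44))
    return "\n".join(lines)


class FitResultsMixin:
    """Adds ``params``/``bse`` dict views and ``summary()`` to results classes.

    Subclasses set ``_param_names`` (attribute names of point estimates;
    ``<name>_se`` attributes, where present, become the standard errors),
    ``_title`` and optionally ``_extra_names``.
    """

    _param_names: tuple[str, ...] = ()
    _extra_names: tuple[str, ...] = ()
    _title: str = "Fit results"

    @property
    def params(self) -> dict[str, float]:
        return {n: getattr(self, n) for n in self._param_names}

    @property
    def bse(self) -> dict[str, float]:
        out = {}
        for n in self._param_names:
            out[n] = getattr(self, f"{n}_se", float("nan"))
        return out

    def summary(self) -> str:
        extra = {n: getattr(self, n) for n in self._extra_names if getattr(self, n, None) is not None}
        return summary_table(self._title, self.params, self.bse, extra)
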