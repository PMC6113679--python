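"""Reading and writing JCAMP-DX spectra.

Supports single- and multi-block files, ``##XYDATA=(X++(Y..Y))`` tables in
AFFN or packed ASDF form (SQZ/DIF/DUP), and ``##XYPOINTS=(XY..XY)``. X/Y
factors are applied on read; spectra are written back as plain AFFN with unit
factors, which round-trips exactly.

The infobox fields of :class:`~addftir.spectra.SpectrumMetadata` travel in
``##$``-prefixed user records (``##$ABBREVIATION`` etc.).
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Sequence

import numpy as np

from .spectra import AcquisitionMethod, Spectrum, SpectrumMetadata, WavenumberGrid

__all__ = ["read_jcampdx", "write_jcampdx", "JcampParseError"]


class JcampParseError(ValueError):
    """Raised when a JCAMP-DX file is malformed."""


_SQZ = {"@": 0}
_SQZ.update({chr(ord("A") + i): i + 1 for i in range(9)})
_SQZ.update({chr(ord("a") + i): -(i + 1) for i in range(9)})
_DIF = {"%": 0}
_DIF.update({chr(ord("J") + i): i + 1 for i in range(9)})
_DIF.update({chr(ord("j") + i): -(i + 1) for i in range(9)})
_DUP = {chr(ord("S") + i): i + 1 for i in range(8)}
_DUP["s"] = 9


def _tokenize_asdf(line: str) -> list[tuple[str, float]]:
    """Split an ASDF data line into (mode, value) tokens.

    mode is 'n' (plain AFFN number), 's' (SQZ), 'd' (DIF delta) or
    'u' (DUP count).
    """
    tokens: list[tuple[str, float]] = []
    i, n = 0, len(line)
    while i < n:
        c = line[i]
        if c in " \t,;":
            i += 1
            continue
        if c in "+-" or c.isdigit() or c == ".":
            j = i + 1 if c in "+-" else i
            k = j
            while k < n and (line[k].isdigit() or line[k] == "."):
                k += 1
            # AFFN exponent: E/e directly followed by optional sign + digit,
            # preceded by a digit (never generated by packed forms we emit)
            if (
                k < n
                and line[k] in "Ee"
                and k > j
                and line[k - 1].isdigit()
                and k + 1 < n
                and (line[k + 1].isdigit() or (line[k + 1] in "+-" and k + 2 < n and line[k + 2].isdigit()))
            ):
                k += 2
                while k < n and line[k].isdigit():
                    k += 1
            if k == j:
                raise JcampParseError(f"dangling sign in data line: {line!r}")
            tokens.append(("n", float(line[i:k])))
            i = k
        elif c in _SQZ or c in _DIF or c in _DUP:
            if c in _SQZ:
                mode, lead = "s", _SQZ[c]
            elif c in _DIF:
                mode, lead = "d", _DIF[c]
            else:
                mode, lead = "u", _DUP[c]
            k = i + 1
            while k < n and (line[k].isdigit() or line[k] == "."):
                k += 1
            digits = line[i + 1 : k]
            value = float(f"{lead}{digits}" if lead >= 0 else f"-{-lead}{digits}")
            tokens.append((mode, value))
            i = k
        elif c == "?":
            raise JcampParseError("missing datapoint marker '?' in table")
        else:
            raise JcampParseError(f"unexpected character {c!r} in data line")
    return tokens


def _decode_xydata(lines: list[str], npoints: int) -> np.ndarray:
    """Decode ``(X++(Y..Y))`` lines into raw Y values (factors not applied)."""
    ys: list[float] = []
    last_was_dif = False
    for line in lines:
        tokens = _tokenize_asdf(line)
        if not tokens or tokens[0][0] != "n":
            raise JcampParseError(f"data line lacks leading X value: {line!r}")
        first = True
        for mode, value in tokens[1:]:
            if mode == "n" or mode == "s":
                if last_was_dif and first:
                    # X-sequence check value duplicating the previous Y
                    if ys and abs(value - ys[-1]) > max(1.0, abs(ys[-1])) * 1e-6:
                        raise JcampParseError(
                            "DIF checkpoint mismatch between data lines"
                        )
                    last_was_dif = False
                    first = False
                    continue
                ys.append(value)
                last_was_dif = False
            elif mode == "d":
                if not ys:
                    raise JcampParseError("DIF delta with no preceding value")
                ys.append(ys[-1] + value)
                last_was_dif = True
            elif mode == "u":
                if not ys:
                    raise JcampParseError("DUP with no preceding value")
                # DUP repeats the previous ordinate operation
                reps = int(value) - 1
                if last_was_dif:
                    delta = ys[-1] - ys[-2]
                    for _ in range(reps):
                        ys.append(ys[-1] + delta)
                else:
                    for _ in range(reps):
                        ys.append(ys[-1])
            first = False
    if len(ys) != npoints:
        raise JcampParseError(
            f"##NPOINTS declares {npoints} points but table holds {len(ys)}"
        )
    return np.asarray(ys, dtype=float)


def _decode_xypoints(lines: list[str], npoints: int) -> tuple[np.ndarray, np.ndarray]:
    nums: list[float] = []
    for line in lines:
        for mode, value in _tokenize_asdf(line):
            if mode != "n":
                raise JcampParseError("packed forms are not valid in XYPOINTS")
            nums.append(value)
    if len(nums) != 2 * npoints:
        raise JcampParseError(
            f"##NPOINTS declares {npoints} pairs but table holds {len(nums)} numbers"
        )
    arr = np.asarray(nums, dtype=float).reshape(-1, 2)
    return arr[:, 0], arr[:, 1]


_LDR = re.compile(r"^##(?P<label>[^=]*)=(?P<value>.*)$")


def _parse_block(block_lines: list[str]) -> Spectrum:
    headers: dict[str, str] = {}
    table_kind: str | None = None
    table_lines: list[str] = []
    in_table = False
    for raw in block_lines:
        line = raw.split("$$", 1)[0].rstrip()
        if not line:
            continue
        m = _LDR.match(line)
        if m:
            label = m.group("label").strip().upper().replace(" ", "")
            value = m.group("value").strip()
            if label in ("XYDATA", "XYPOINTS"):
                table_kind = label
                in_table = True
                headers[label] = value
            elif label == "END":
                in_table = False
            else:
                in_table = False
                headers[label] = value
        elif in_table:
            table_lines.append(line)
    if table_kind is None:
        raise JcampParseError("block declares no ##XYDATA or ##XYPOINTS table")

    def fget(key: str, default: float | None = None) -> float:
        if key in headers:
            try:
                return float(headers[key])
            except ValueError as exc:
                raise JcampParseError(f"##{key} is not numeric: {headers[key]!r}") from exc
        if default is None:
            raise JcampParseError(f"required record ##{key} missing")
        return default

    xfactor = fget("XFACTOR", 1.0)
    yfactor = fget("YFACTOR", 1.0)
    npoints = int(fget("NPOINTS"))
    if npoints < 2:
        raise JcampParseError("##NPOINTS must be >= 2")
    if table_kind == "XYDATA":
        firstx = fget("FIRSTX")
        lastx = fget("LASTX")
        y_raw = _decode_xydata(table_lines, npoints)
        x = np.linspace(firstx, lastx, npoints)
        y = y_raw * yfactor
    else:
        x_raw, y_raw = _decode_xypoints(table_lines, npoints)
        x = x_raw * xfactor
        y = y_raw * yfactor

    method = headers.get("$METHOD", "ATR")
    try:
        method_enum = AcquisitionMethod(method)
    except ValueError:
        method_enum = AcquisitionMethod.ATR
    meta = SpectrumMetadata(
        sample_name=headers.get("TITLE", "unnamed") or "unnamed",
        abbreviation=headers.get("$ABBREVIATION", ""),
        supplier=headers.get("$SUPPLIER", ""),
        source_id=headers.get("$SOURCEID", ""),
        form=headers.get("$FORM", ""),
        color=headers.get("$COLOR", ""),
        method=method_enum,
    )
    order = np.argsort(x)[::-1]  # store descending
    return Spectrum(grid=WavenumberGrid(x[order]), intensities=y[order], metadata=meta)


def read_jcampdx(path: str | Path) -> Spectrum | list[Spectrum]:
    """Read a JCAMP-DX file; multi-block (LINK) files yield a list."""
    text = Path(path).read_text()
    lines = text.splitlines()
    # split on ##TITLE= records; a LINK outer block (no data table) is dropped
    starts = [i for i, ln in enumerate(lines) if ln.upper().startswith("##TITLE")]
    if not starts:
        raise JcampParseError(f"{path}: no ##TITLE record found")
    blocks: list[list[str]] = []
    for n, start in enumerate(starts):
        stop = starts[n + 1] if n + 1 < len(starts) else len(lines)
        blocks.append(lines[start:stop])
    spectra: list[Spectrum] = []
    for block in blocks:
        has_table = any(
            ln.upper().replace(" ", "").startswith(("##XYDATA=", "##XYPOINTS="))
            for ln in block
        )
        if not has_table:
            continue  # LINK wrapper block
        try:
            spectra.append(_parse_block(block))
        except JcampParseError as exc:
            raise JcampParseError(f"{path}: {exc}") from exc
    if not spectra:
        raise JcampParseError(f"{path}: no data blocks found")
    return spectra[0] if len(spectra) == 1 else spectra


def _fmt(v: float) -> str:
    return np.format_float_positional(v, trim="-")


def _write_block(spectrum: Spectrum, per_line: int = 6) -> list[str]:
    m = spectrum.metadata
    x = spectrum.grid.values
    y = spectrum.intensities
    out = [
        f"##TITLE={m.sample_name}",
        "##JCAMP-DX=4.24",
        "##DATA TYPE=INFRARED SPECTRUM",
        "##XUNITS=1/CM",
        "##YUNITS=ABSORBANCE",
        f"##$ABBREVIATION={m.abbreviation}",
        f"##$SUPPLIER={m.supplier}",
        f"##$SOURCEID={m.source_id}",
        f"##$FORM={m.form}",
        f"##$COLOR={m.color}",
        f"##$METHOD={m.method.value}",
        "##XFACTOR=1",
        "##YFACTOR=1",
        f"##FIRSTX={_fmt(x[0])}",
        f"##LASTX={_fmt(x[-1])}",
        f"##NPOINTS={len(x)}",
        f"##FIRSTY={_fmt(y[0])}",
        "##XYDATA=(X++(Y..Y))",
    ]
    for i in range(0, len(x), per_line):
        ys = " ".join(_fmt(v) for v in y[i : i + per_line])
        out.append(f"{_fmt(x[i])} {ys}")
    out.append("##END=")
    return out


def write_jcampdx(spectra: Spectrum | Sequence[Spectrum], path: str | Path) -> Path:
    """Write one or more spectra as a (multi-block) JCAMP-DX file."""
    path = Path(path)
    if isinstance(spectra, Spectrum):
        lines = _write_block(spectra)
    else:
        if len(spectra) == 0:
            raise ValueError("no spectra to write")
        if len(spectra) == 1:
            lines = _write_block(spectra[0])
        else:
            lines = [
                "##TITLE=addftir spectrum collection",
                "##JCAMP-DX=4.24",
                "##DATA TYPE=LINK",
                f"##BLOCKS={len(spectra)}",
            ]
            for s in spectra:
                lines.extend(_write_block(s))
            lines.append("##END=")
    path.write_text("\n".join(lines) + "\n")
    return path
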