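"""Minimal read-only JCAMP-DX import for UV-Vis spectra.

Supports the plain-text (AFFN) encodings an instrument export typically
uses: ``##XYDATA=(X++(Y..Y))`` with ``FIRSTX``/``LASTX``/``NPOINTS`` and
optional ``XFACTOR``/``YFACTOR``, and ``##XYPOINTS=(XY..XY)`` pairs.
Compressed (SQZ/DIF/DUP) encodings are out of scope.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np


def _parse_records(text: str) -> tuple[dict[str, str], list[tuple[str, list[str]]]]:
    """Split a JCAMP file into labelled data records (``##LABEL=value``)."""
    header: dict[str, str] = {}
    blocks: list[tuple[str, list[str]]] = []
    current: tuple[str, list[str]] | None = None
    for raw in text.splitlines():
        line = raw.split("$$", 1)[0].rstrip()  # strip inline comments
        if not line:
            continue
        if line.startswith("##"):
            label, _, value = line[2:].partition("=")
            label = re.sub(r"[\s_-]", "", label).upper()
            value = value.strip()
            if label in ("XYDATA", "XYPOINTS", "PEAKTABLE"):
                current = (label, [])
                blocks.append(current)
            else:
                current = None
                header[label] = value
        elif current is not None:
            current[1].append(line)
    return header, blocks


def read_jcamp(path: str | Path):
    """Read a JCAMP-DX file and return a :class:`~duospec.spectrum.Spectrum`."""
    from .spectrum import Spectrum, SpectrumError

    text = Path(path).read_text()
    header, blocks = _parse_records(text)
    if not blocks:
        raise SpectrumError(f"{path}: no XYDATA/XYPOINTS block found")
    kind_label, lines = blocks[0]
    xfactor = float(header.get("XFACTOR", 1.0))
    yfactor = float(header.get("YFACTOR", 1.0))

    xs: list[float] = []
    ys: list[float] = []
    if kind_label == "XYDATA":
        npoints = int(float(header["NPOINTS"]))
        firstx = float(header["FIRSTX"])
        lastx = float(header["LASTX"])
        for line in lines:
            vals = [float(v) for v in re.split(r"[,\s]+", line.strip()) if v]
            if not vals:
                continue
            ys.extend(vals[1:])  # first value per line is the line's X
        if len(ys) != npoints:
            raise SpectrumError(
                f"{path}: NPOINTS={npoints} but {len(ys)} ordinates found"
            )
        x = np.linspace(firstx * xfactor, lastx * xfactor, npoints)
        y = np.asarray(ys) * yfactor
    else:  # (XY..XY) pairs
        for line in lines:
            vals = [float(v) for v in re.split(r"[,;\s]+", line.strip()) if v]
            xs.extend(vals[0::2])
            ys.extend(vals[1::2])
        x = np.asarray(xs) * xfactor
        y = np.asarray(ys) * yfactor

    if x[0] > x[-1]:  # instruments often scan long-to-short wavelength
        x = x[::-1]
        y = y[::-1]
    conc = header.get("CONCENTRATION")
    conc_value = None
    if conc:
        m = re.search(r"[-+0-9.eE]+", conc)
        if m:
            conc_value = float(m.group())
    return Spectrum(
        wavelengths=x,
        absorbances=y,
        label=header.get("TITLE", ""),
        concentration=conc_value,
    )
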