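"""Minimal EDF+ writer/reader (16-bit, single continuous recording).

Covers what the pipeline needs — multichannel signals at one sampling
rate plus sample-accurate event annotations — not the full spec (no
discontinuous files, no per-signal rates). No third-party EDF library
is assumed.
"""

from __future__ import annotations

import math

import numpy as np

from .errors import FormatError

_ANNOT_LABEL = "EDF Annotations"


def _field(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise FormatError(f"header field '{s}' exceeds {width} bytes")
    return s.ljust(width).encode("ascii")


def write_edf(path, data: np.ndarray, fs: float, channel_labels,
              events=(), record_duration: float = 1.0,
              start="01.01.00", time="00.00.00"):
    """Write ``data`` (channels x samples) as EDF+C.

    Events are ``(onset_seconds, label)`` pairs stored in an annotation
    signal. The last data record is zero-padded when the sample count is
    not a whole number of records.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    n_ch, n_samp = data.shape
    if len(channel_labels) != n_ch:
        raise FormatError("one label per channel required")
    spr = int(round(fs * record_duration))
    if abs(spr - fs * record_duration) > 1e-9:
        raise FormatError("fs * record_duration must be an integer")
    n_rec = max(1, math.ceil(n_samp / spr))

    # physical/digital scaling per channel
    pmins, pmaxs = [], []
    digital = np.empty((n_ch, n_rec * spr), dtype="<i2")
    for c in range(n_ch):
        lo = float(np.min(data[c])) if n_samp else -1.0
        hi = float(np.max(data[c])) if n_samp else 1.0
        if hi <= lo:
            hi = lo + 1.0
        pmins.append(lo)
        pmaxs.append(hi)
        scaled = (data[c] - lo) / (hi - lo) * 65535.0 - 32768.0
        row = np.zeros(n_rec * spr, dtype="<i2")
        row[:n_samp] = np.round(scaled).astype("<i2")
        digital[c] = row

    # annotation payload per record: timestamp TAL + any events due
    annots = []
    by_record: dict[int, list] = {}
    for onset, label in events:
        by_record.setdefault(int(onset // record_duration), []).append(
            (float(onset), str(label)))
    for r in range(n_rec):
        tal = f"+{r * record_duration:g}\x14\x14\x00"
        for onset, label in sorted(by_record.get(r, [])):
            tal += f"+{onset:.6f}\x14{label}\x14\x00"
        annots.append(tal.encode("utf-8"))
    annot_bytes = max(max((len(a) for a in annots), default=2), 2)
    annot_spr = (annot_bytes + 1) // 2 + 8  # headroom, in 2-byte samples

    ns = n_ch + 1
    header_bytes = 256 * (ns + 1)
    with open(path, "wb") as fh:
        fh.write(_field("0", 8))
        fh.write(_field("synthetic", 80))
        fh.write(_field("eeglrtc", 80))
        fh.write(_field(start, 8))
        fh.write(_field(time, 8))
        fh.write(_field(header_bytes, 8))
        fh.write(_field("EDF+C", 44))
        fh.write(_field(n_rec, 8))
        fh.write(_field(f"{record_duration:g}", 8))
        fh.write(_field(ns, 4))

        labels = list(channel_labels) + [_ANNOT_LABEL]
        for lab in labels:
            fh.write(_field(lab, 16))
        for _ in labels:
            fh.write(_field("", 80))         # transducer
        for c in range(ns):
            fh.write(_field("uV" if c < n_ch else "", 8))
        for c in range(ns):
            fh.write(_field(f"{pmins[c]:.6g}" if c < n_ch else -1, 8))
        for c in range(ns):
            fh.write(_field(f"{pmaxs[c]:.6g}" if c < n_ch else 1, 8))
        for c in range(ns):
            fh.write(_field(-32768, 8))
        for c in range(ns):
            fh.write(_field(32767, 8))
        for _ in labels:
            fh.write(_field("", 80))         # prefiltering
        for c in range(ns):
            fh.write(_field(spr if c < n_ch else annot_spr, 8))
        for _ in labels:
            fh.write(_field("", 32))

        for r in range(n_rec):
            for c in range(n_ch):
                fh.write(digital[c, r * spr:(r + 1) * spr].tobytes())
            pad = annots[r].ljust(annot_spr * 2, b"\x00")
            fh.write(pad)


def read_edf(path):
    """Read an EDF/EDF+ file written by :func:`write_edf`.

    Returns ``(data, fs, labels, events)`` with ``data`` of shape
    (channels, samples) in physical units and ``events`` a list of
    ``(onset_seconds, label)``.
    """
    with open(path, "rb") as fh:
        head = fh.read(256)
        if len(head) < 256:
            raise FormatError("truncated EDF header")
        try:
            n_rec = int(head[236:244].decode("ascii").strip())
            rec_dur = float(head[244:252].decode("ascii").strip())
            ns = int(head[252:256].decode("ascii").strip())
        except ValueError as exc:
            raise FormatError(f"malformed EDF header: {exc}") from exc
        sig = fh.read(256 * ns)
        if len(sig) < 256 * ns:
            raise FormatError("truncated EDF signal header")

        def col(offset, width):
            base = offset * ns
            return [sig[base + i * width: base + (i + 1) * width]
                    .decode("ascii", "replace").strip() for i in range(ns)]

        labels = col(0, 16)
        pmin = col(16 + 80 + 8, 8)
        pmax = col(16 + 80 + 8 + 8, 8)
        dmin = col(16 + 80 + 8 + 16, 8)
        dmax = col(16 + 80 + 8 + 24, 8)
        spr = [int(v) for v in col(16 + 80 + 8 + 32 + 80, 8)]

        is_annot = [lab == _ANNOT_LABEL for lab in labels]
        raw = {i: [] for i in range(ns)}
        for _ in range(n_rec):
            for i in range(ns):
                chunk = fh.read(2 * spr[i])
                if len(chunk) < 2 * spr[i]:
                    raise FormatError("truncated EDF data record")
                raw[i].append(chunk)

    data, out_labels, events = [], [], []
    fs = None
    for i in range(ns):
        if is_annot[i]:
            for chunk in raw[i]:
                for tal in chunk.split(b"\x00"):
                    if not tal:
                        continue
                    parts = tal.decode("utf-8", "replace").split("\x14")
                    if len(parts) < 2 or not parts[0]:
                        continue
                    onset = float(parts[0].split("\x15")[0])
                    for label in parts[1:]:
                        if label:
                            events.append((onset, label))
            continue
        digi = np.frombuffer(b"".join(raw[i]), dtype="<i2").astype(float)
        lo, hi = float(pmin[i]), float(pmax[i])
        dlo, dhi = float(dmin[i]), float(dmax[i])
        data.append(lo + (digi - dlo) * (hi - lo) / (dhi - dlo))
        out_labels.append(labels[i])
        fs = spr[i] / rec_dur
    return np.array(data), fs, out_labels, events
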