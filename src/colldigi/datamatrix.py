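"""ECC200 DataMatrix encoding and decoding.

Specimen identifiers are printed as 2-D DataMatrix symbols on the label that
sits in the right-hand panel of each photograph, and the overnight batch
process has to read them back out of JPEG crops.  This module implements the
square ECC200 symbol family up to 26x26 modules (one data region, one
Reed-Solomon block), which comfortably covers the short alphanumeric payloads
used as collection barcodes:

* ASCII encodation (digit-pair packing, 253-state pad randomisation),
* the standard "utah"/corner bit-placement of the data region,
* Reed-Solomon error correction over GF(256) with primitive polynomial 0x12D,
* rendering a symbol into a greyscale pixel array, and
* locating and decoding symbols inside a larger greyscale image (the label
  crop), tolerant of the four upright rotations and mild JPEG noise.

Decoding returns the payload string, or ``None`` when no symbol validates --
a damaged symbol is a *failure signal*, not an exception, because unreadable
barcodes are an expected, counted event in batch processing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

# ---------------------------------------------------------------------------
# Symbol geometry: square ECC200 sizes with a single data region.
# size -> (data codewords, error-correction codewords)
# ---------------------------------------------------------------------------

SYMBOL_SIZES: dict[int, tuple[int, int]] = {
    10: (3, 5),
    12: (5, 7),
    14: (8, 10),
    16: (12, 12),
    18: (18, 14),
    20: (22, 18),
    22: (30, 20),
    24: (36, 24),
    26: (44, 28),
}

PAD = 129  # ASCII-mode pad codeword

# ---------------------------------------------------------------------------
# GF(256) arithmetic, primitive polynomial x^8 + x^5 + x^3 + x^2 + 1 (0x12D)
# ---------------------------------------------------------------------------

_GF_EXP = np.zeros(512, dtype=np.int64)
_GF_LOG = np.zeros(256, dtype=np.int64)


def _init_tables() -> None:
    x = 1
    for i in range(255):
        _GF_EXP[i] = x
        _GF_LOG[x] = i
        x <<= 1
        if x & 0x100:
            x ^= 0x12D
    for i in range(255, 512):
        _GF_EXP[i] = _GF_EXP[i - 255]


_init_tables()


def _gf_mul(a: int, b: int) -> int:
    if a == 0 or b == 0:
        return 0
    return int(_GF_EXP[_GF_LOG[a] + _GF_LOG[b]])


def _gf_inv(a: int) -> int:
    return int(_GF_EXP[255 - _GF_LOG[a]])


def _rs_generator(nsym: int) -> list[int]:
    # roots alpha^1 .. alpha^nsym (first consecutive root index 1)
    g = [1]
    for i in range(1, nsym + 1):
        root = int(_GF_EXP[i])
        ng = [0] * (len(g) + 1)
        for j, c in enumerate(g):
            ng[j] ^= _gf_mul(c, root)
            ng[j + 1] ^= c
        g = ng
    return g[::-1]  # descending powers, leading coefficient first


def rs_encode(data: list[int], nsym: int) -> list[int]:
    """Append ``nsym`` Reed-Solomon check codewords to ``data``."""
    gen = _rs_generator(nsym)
    rem = [0] * nsym
    for d in data:
        factor = d ^ rem[0]
        rem = rem[1:] + [0]
        if factor:
            for j in range(nsym):
                rem[j] ^= _gf_mul(gen[j + 1], factor)
    return list(data) + rem


def _gf_pow(power: int) -> int:
    return int(_GF_EXP[power % 255])


def _poly_scale(p: list[int], x: int) -> list[int]:
    return [_gf_mul(c, x) for c in p]


def _poly_add(p: list[int], q: list[int]) -> list[int]:
    r = [0] * max(len(p), len(q))
    for i, c in enumerate(p):
        r[i + len(r) - len(p)] = c
    for i, c in enumerate(q):
        r[i + len(r) - len(q)] ^= c
    return r


def _poly_mul(p: list[int], q: list[int]) -> list[int]:
    r = [0] * (len(p) + len(q) - 1)
    for j, qc in enumerate(q):
        for i, pc in enumerate(p):
            r[i + j] ^= _gf_mul(pc, qc)
    return r


def _poly_eval(p: list[int], x: int) -> int:
    # p[0] is the highest-degree coefficient
    y = p[0]
    for c in p[1:]:
        y = _gf_mul(y, x) ^ c
    return y


def _rs_syndromes(code: list[int], nsym: int) -> list[int]:
    # roots alpha^1 .. alpha^nsym; leading zero pad for index bookkeeping
    return [0] + [_poly_eval(code, _gf_pow(i + 1)) for i in range(nsym)]


def _find_error_locator(synd: list[int], nsym: int) -> list[int] | None:
    err_loc = [1]
    old_loc = [1]
    synd_shift = len(synd) - nsym
    for i in range(nsym):
        k = i + synd_shift
        delta = synd[k]
        for j in range(1, len(err_loc)):
            delta ^= _gf_mul(err_loc[-(j + 1)], synd[k - j])
        old_loc.append(0)
        if delta != 0:
            if len(old_loc) > len(err_loc):
                new_loc = _poly_scale(old_loc, delta)
                old_loc = _poly_scale(err_loc, _gf_inv(delta))
                err_loc = new_loc
            err_loc = _poly_add(err_loc, _poly_scale(old_loc, delta))
    while len(err_loc) > 1 and err_loc[0] == 0:
        err_loc.pop(0)
    n_errors = len(err_loc) - 1
    if n_errors * 2 > nsym:
        return None
    return err_loc


def _find_errors(err_loc_rev: list[int], nmess: int) -> list[int] | None:
    n_errors = len(err_loc_rev) - 1
    err_pos = []
    for i in range(nmess):
        if _poly_eval(err_loc_rev, _gf_pow(i)) == 0:
            err_pos.append(nmess - 1 - i)
    if len(err_pos) != n_errors:
        return None
    return err_pos


def rs_correct(code: list[int], nsym: int) -> list[int] | None:
    """Correct up to ``nsym // 2`` codeword errors.

    Returns the corrected codeword list, or ``None`` when the block is
    uncorrectable (the caller treats this as a decode failure).
    """
    synd = _rs_syndromes(code, nsym)
    if max(synd) == 0:
        return list(code)
    err_loc = _find_error_locator(synd, nsym)
    if err_loc is None:
        return None
    err_pos = _find_errors(err_loc[::-1], len(code))
    if not err_pos:
        return None
    out = _correct_errata(list(code), synd, err_pos)
    if out is None or max(_rs_syndromes(out, nsym)) != 0:
        return None
    return out


def _correct_errata(msg: list[int], synd: list[int], err_pos: list[int]) -> list[int] | None:
    # Forney algorithm; first consecutive root is alpha^1 (fcr = 1)
    coef_pos = [len(msg) - 1 - p for p in err_pos]
    loc = [1]
    for i in coef_pos:
        loc = _poly_mul(loc, _poly_add([1], [_gf_pow(i), 0]))
    # error evaluator: (synd_rev * loc) mod x^(len(loc))
    prod = _poly_mul(synd[::-1], loc)
    err_eval = prod[-len(loc) :]
    x_vals = [_gf_pow(-(255 - c)) for c in coef_pos]
    for i, xi in enumerate(x_vals):
        xi_inv = _gf_inv(xi)
        loc_prime = 1
        for j, xj in enumerate(x_vals):
            if j != i:
                loc_prime = _gf_mul(loc_prime, 1 ^ _gf_mul(xi_inv, xj))
        if loc_prime == 0:
            return None
        y = _poly_eval(err_eval, xi_inv) if err_eval else 0
        y = _gf_mul(y, 1)  # X_i^(1 - fcr) with fcr = 1
        msg[err_pos[i]] ^= _gf_mul(y, _gf_inv(loc_prime))
    return msg


# ---------------------------------------------------------------------------
# ASCII encodation
# ---------------------------------------------------------------------------


def _ascii_encode(text: str) -> list[int]:
    cws: list[int] = []
    i = 0
    while i < len(text):
        c = text[i]
        if c.isdigit() and i + 1 < len(text) and text[i + 1].isdigit():
            cws.append(int(text[i : i + 2]) + 130)
            i += 2
        else:
            o = ord(c)
            if o > 127:
                raise ValueError(f"non-ASCII character {c!r} in payload")
            cws.append(o + 1)
            i += 1
    return cws


def _pad(cws: list[int], capacity: int) -> list[int]:
    out = list(cws)
    if len(out) < capacity:
        out.append(PAD)
    while len(out) < capacity:
        # 253-state pad randomisation, position is 1-based
        pseudo = ((149 * (len(out) + 1)) % 253) + 1
        v = PAD + pseudo
        if v > 254:
            v -= 254
        out.append(v)
    return out


def _ascii_decode(cws: list[int]) -> str | None:
    out: list[str] = []
    for cw in cws:
        if cw == 0:
            return None
        if cw == PAD:
            break
        if 1 <= cw <= 128:
            out.append(chr(cw - 1))
        elif 130 <= cw <= 229:
            out.append(f"{cw - 130:02d}")
        else:
            # mode-switch codewords (C40, Base256, ...) are never emitted by
            # this encoder; treat them as an invalid symbol
            return None
    return "".join(out)


# ---------------------------------------------------------------------------
# ECC200 bit placement (standard "utah" walk over the data region)
# ---------------------------------------------------------------------------

_FIXED_DARK = ("F", 1)
_FIXED_LIGHT = ("F", 0)


def _placement_grid(nrow: int, ncol: int) -> list[list[tuple]]:
    grid: list[list[tuple | None]] = [[None] * ncol for _ in range(nrow)]

    def module(r, c, idx, bit):
        if r < 0:
            r += nrow
            c += 4 - ((nrow + 4) % 8)
        if c < 0:
            c += ncol
            r += 4 - ((ncol + 4) % 8)
        grid[r][c] = (idx, bit)

    def utah(r, c, idx):
        module(r - 2, c - 2, idx, 0)
        module(r - 2, c - 1, idx, 1)
        module(r - 1, c - 2, idx, 2)
        module(r - 1, c - 1, idx, 3)
        module(r - 1, c, idx, 4)
        module(r, c - 2, idx, 5)
        module(r, c - 1, idx, 6)
        module(r, c, idx, 7)

    def corner1(idx):
        module(nrow - 1, 0, idx, 0)
        module(nrow - 1, 1, idx, 1)
        module(nrow - 1, 2, idx, 2)
        module(0, ncol - 2, idx, 3)
        module(0, ncol - 1, idx, 4)
        module(1, ncol - 1, idx, 5)
        module(2, ncol - 1, idx, 6)
        module(3, ncol - 1, idx, 7)

    def corner2(idx):
        module(nrow - 3, 0, idx, 0)
        module(nrow - 2, 0, idx, 1)
        module(nrow - 1, 0, idx, 2)
        module(0, ncol - 4, idx, 3)
        module(0, ncol - 3, idx, 4)
        module(0, ncol - 2, idx, 5)
        module(0, ncol - 1, idx, 6)
        module(1, ncol - 1, idx, 7)

    def corner3(idx):
        module(nrow - 3, 0, idx, 0)
        module(nrow - 2, 0, idx, 1)
        module(nrow - 1, 0, idx, 2)
        module(0, ncol - 2, idx, 3)
        module(0, ncol - 1, idx, 4)
        module(1, ncol - 1, idx, 5)
        module(2, ncol - 1, idx, 6)
        module(3, ncol - 1, idx, 7)

    def corner4(idx):
        module(nrow - 1, 0, idx, 0)
        module(nrow - 1, ncol - 1, idx, 1)
        module(0, ncol - 3, idx, 2)
        module(0, ncol - 2, idx, 3)
        module(0, ncol - 1, idx, 4)
        module(1, ncol - 3, idx, 5)
        module(1, ncol - 2, idx, 6)
        module(1, ncol - 1, idx, 7)

    idx = 1
    r, c = 4, 0
    while True:
        if r == nrow and c == 0:
            corner1(idx)
            idx += 1
        if r == nrow - 2 and c == 0 and ncol % 4:
            corner2(idx)
            idx += 1
        if r == nrow - 2 and c == 0 and ncol % 8 == 4:
            corner3(idx)
            idx += 1
        if r == nrow + 4 and c == 2 and not (ncol % 8):
            corner4(idx)
            idx += 1
        while True:
            if r < nrow and c >= 0 and grid[r][c] is None:
                utah(r, c, idx)
                idx += 1
            r -= 2
            c += 2
            if not (r >= 0 and c < ncol):
                break
        r += 1
        c += 3
        while True:
            if r >= 0 and c < ncol and grid[r][c] is None:
                utah(r, c, idx)
                idx += 1
            r += 2
            c -= 2
            if not (r < nrow and c >= 0):
                break
        r += 3
        c += 1
        if not (r < nrow or c < ncol):
            break
    if grid[nrow - 1][ncol - 1] is None:
        grid[nrow - 1][ncol - 1] = _FIXED_DARK
        grid[nrow - 2][ncol - 2] = _FIXED_DARK
        grid[nrow - 1][ncol - 2] = _FIXED_LIGHT
        grid[nrow - 2][ncol - 1] = _FIXED_LIGHT
    return grid  # type: ignore[return-value]


# ---------------------------------------------------------------------------
# Matrix-level encode / decode
# ---------------------------------------------------------------------------


def _choose_size(n_data: int) -> int:
    for size, (cap, _) in SYMBOL_SIZES.items():
        if cap >= n_data:
            return size
    raise ValueError(f"payload needs {n_data} codewords, exceeds 26x26 capacity")


def encode_matrix(text: str, size: int | None = None) -> np.ndarray:
    """Encode ``text`` into a boolean module matrix (True = dark module)."""
    data = _ascii_encode(text)
    if size is None:
        size = _choose_size(len(data))
    if size not in SYMBOL_SIZES:
        raise ValueError(f"unsupported symbol size {size}")
    cap, nsym = SYMBOL_SIZES[size]
    if len(data) > cap:
        raise ValueError(f"payload too long for {size}x{size} symbol")
    codewords = rs_encode(_pad(data, cap), nsym)

    n = size - 2
    grid = _placement_grid(n, n)
    mat = np.zeros((size, size), dtype=bool)
    # finder pattern: solid left column and bottom row, alternating top/right
    mat[:, 0] = True
    mat[size - 1, :] = True
    mat[0, ::2] = True
    mat[1::2, size - 1] = True
    for r in range(n):
        for c in range(n):
            cell = grid[r][c]
            if cell[0] == "F":
                bit = cell[1]
            else:
                idx, bitpos = cell
                bit = (codewords[idx - 1] >> (7 - bitpos)) & 1
            mat[r + 1, c + 1] = bool(bit)
    return mat


def decode_matrix(mat: np.ndarray) -> str | None:
    """Decode an upright boolean module matrix; ``None`` if invalid."""
    size = mat.shape[0]
    if mat.shape[0] != mat.shape[1] or size not in SYMBOL_SIZES:
        return None
    cap, nsym = SYMBOL_SIZES[size]
    n = size - 2
    grid = _placement_grid(n, n)
    codewords = [0] * (cap + nsym)
    for r in range(n):
        for c in range(n):
            cell = grid[r][c]
            if cell[0] == "F":
                continue
            idx, bitpos = cell
            if mat[r + 1, c + 1]:
                codewords[idx - 1] |= 1 << (7 - bitpos)
    corrected = rs_correct(codewords, nsym)
    if corrected is None:
        return None
    return _ascii_decode(corrected[:cap])


def _finder_score(mat: np.ndarray) -> float:
    """Fraction of finder-pattern modules matching the upright convention."""
    size = mat.shape[0]
    expect_left = np.ones(size, dtype=bool)
    expect_bottom = np.ones(size, dtype=bool)
    expect_top = np.zeros(size, dtype=bool)
    expect_top[::2] = True
    expect_right = np.zeros(size, dtype=bool)
    expect_right[1::2] = True
    hits = (
        np.count_nonzero(mat[:, 0] == expect_left)
        + np.count_nonzero(mat[size - 1, :] == expect_bottom)
        + np.count_nonzero(mat[0, :] == expect_top)
        + np.count_nonzero(mat[:, size - 1] == expect_right)
    )
    return hits / (4 * size)


# ---------------------------------------------------------------------------
# Image-level render / detect / decode
# ---------------------------------------------------------------------------

QUIET_ZONE = 2  # modules of light border around the symbol


def render(
    text: str,
    module_px: int = 8,
    dark: int = 15,
    light: int = 250,
    size: int | None = None,
) -> np.ndarray:
    """Render a payload to a uint8 greyscale pixel array with a quiet zone."""
    mat = encode_matrix(text, size=size)
    n = mat.shape[0] + 2 * QUIET_ZONE
    full = np.zeros((n, n), dtype=bool)
    full[QUIET_ZONE:-QUIET_ZONE, QUIET_ZONE:-QUIET_ZONE] = mat
    img = np.where(full, dark, light).astype(np.uint8)
    return np.kron(img, np.ones((module_px, module_px), dtype=np.uint8))


def _sample_grid(dark: np.ndarray, size: int) -> np.ndarray:
    """Vote each of size x size cells dark/light from a cropped boolean mask."""
    h, w = dark.shape
    mat = np.zeros((size, size), dtype=bool)
    for i in range(size):
        r0 = int(round(i * h / size))
        r1 = max(r0 + 1, int(round((i + 1) * h / size)))
        for j in range(size):
            c0 = int(round(j * w / size))
            c1 = max(c0 + 1, int(round((j + 1) * w / size)))
            cell = dark[r0:r1, c0:c1]
            mat[i, j] = cell.mean() > 0.5
    return mat


def decode_image(arr: np.ndarray, max_symbols: int = 4) -> list[str]:
    """Find and decode DataMatrix symbols in a greyscale uint8 image.

    Returns the decoded payloads (possibly empty).  Candidate regions are
    dark connected components whose bounding box is roughly square; each is
    sampled at every supported module count and every upright rotation, and
    accepted only when the finder pattern matches and the Reed-Solomon block
    verifies, so false positives on text or specimen silhouettes are
    effectively impossible.
    """
    if arr.ndim == 3:
        arr = arr.mean(axis=2).astype(np.uint8)
    lo, hi = int(arr.min()), int(arr.max())
    if hi - lo < 30:  # featureless image
        return []
    dark = arr < (lo + hi) / 2
    labels, n_comp = ndimage.label(dark, structure=np.ones((3, 3), dtype=int))
    if n_comp == 0:
        return []
    slices = ndimage.find_objects(labels)
    sizes = ndimage.sum_labels(dark, labels, index=np.arange(1, n_comp + 1))
    order = np.argsort(sizes)[::-1]
    found: list[str] = []
    for k in order[:40]:
        sl = slices[k]
        h = sl[0].stop - sl[0].start
        w = sl[1].stop - sl[1].start
        if min(h, w) < 18 or not (0.6 < h / w < 1.7):
            continue
        region = dark[sl]
        fill = region.mean()
        if not (0.25 < fill < 0.8):
            continue
        payload = _decode_region(region)
        if payload is not None:
            found.append(payload)
            if len(found) >= max_symbols:
                break
    return found


def _decode_region(region: np.ndarray) -> str | None:
    for size in SYMBOL_SIZES:
        mat = _sample_grid(region, size)
        for _ in range(4):
            if _finder_score(mat) > 0.9:
                payload = decode_matrix(mat)
                if payload:
                    return payload
            mat = np.rot90(mat)
    return None


@dataclass
class DecodeResult:
    """Outcome of barcode reading on one label image."""

    payload: str | None
    n_symbols: int

    @property
    def ok(self) -> bool:
        return self.payload is not None and self.n_symbols == 1


def read_barcode(arr: np.ndarray) -> DecodeResult:
    """Decode the specimen barcode from a label-crop pixel array.

    ``n_symbols > 1`` flags the "two barcodes" data-quality error; zero
    symbols is an ordinary decode failure.
    """
    payloads = decode_image(arr)
    if not payloads:
        return DecodeResult(None, 0)
    return DecodeResult(payloads[0], len(payloads))
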