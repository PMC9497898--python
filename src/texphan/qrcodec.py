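"""Minimal ISO/IEC 18004 (QR code, model 2) encoder and image decoder.

The package embeds QR symbols as 3D-printable texture and measures how well a
virtual MR acquisition preserves the encoded information, so both directions
are needed: a standard-compliant encoder (byte mode, error-correction level M,
versions 1-6) to build ground-truth module matrices, and a decoder able to read
degraded grayscale renderings (blur, noise, bias, resampling) of those symbols.

Encoder and decoder share only the static code tables; the decoder recovers
geometry, format and codewords from the pixel data alone, so an
encode -> degrade -> decode round trip is a genuine end-to-end check.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "QRCapacityError",
    "QRDecodeError",
    "encode_text",
    "decode_matrix",
    "decode_image",
    "render_matrix",
    "qr_version",
]


class QRCapacityError(ValueError):
    """Payload does not fit any supported symbol version."""


class QRDecodeError(ValueError):
    """Image or module matrix could not be decoded."""


# --------------------------------------------------------------------------
# GF(256) arithmetic (primitive polynomial x^8+x^4+x^3+x^2+1 = 0x11d)
# --------------------------------------------------------------------------

_GF_EXP = np.zeros(512, dtype=np.int64)
_GF_LOG = np.zeros(256, dtype=np.int64)
_x = 1
for _i in range(255):
    _GF_EXP[_i] = _x
    _GF_LOG[_x] = _i
    _x <<= 1
    if _x & 0x100:
        _x ^= 0x11D
_GF_EXP[255:510] = _GF_EXP[:255]


def _gf_mul(a: int, b: int) -> int:
    if a == 0 or b == 0:
        return 0
    return int(_GF_EXP[_GF_LOG[a] + _GF_LOG[b]])


def _gf_inv(a: int) -> int:
    return int(_GF_EXP[255 - _GF_LOG[a]])


def _poly_mul_low(p, q):
    # both lowest degree first
    r = [0] * (len(p) + len(q) - 1)
    for i, a in enumerate(p):
        for j, b in enumerate(q):
            r[i + j] ^= _gf_mul(a, b)
    return r


def _poly_mul(p, q):
    r = [0] * (len(p) + len(q) - 1)
    for i, a in enumerate(p):
        for j, b in enumerate(q):
            r[i + j] ^= _gf_mul(a, b)
    return r


def _poly_eval(p, x):
    # p holds coefficients highest degree first
    y = 0
    for c in p:
        y = _gf_mul(y, x) ^ c
    return y


def _rs_generator(nsym: int):
    g = [1]
    for i in range(nsym):
        g = _poly_mul(g, [1, int(_GF_EXP[i])])
    return g


def rs_encode(data: list[int], nsym: int) -> list[int]:
    """Return the ``nsym`` Reed-Solomon parity codewords for ``data``."""
    gen = _rs_generator(nsym)
    rem = list(data) + [0] * nsym
    for i in range(len(data)):
        coef = rem[i]
        if coef:
            for j in range(1, len(gen)):
                rem[i + j] ^= _gf_mul(gen[j], coef)
    return rem[len(data):]


def _poly_eval_low(p, x):
    # p holds coefficients lowest degree first
    y = 0
    xp = 1
    for c in p:
        y ^= _gf_mul(c, xp)
        xp = _gf_mul(xp, x)
    return y


def rs_decode(codeword: list[int], nsym: int) -> list[int]:
    """Correct up to ``nsym // 2`` codeword errors; return the data part.

    Syndrome / Berlekamp-Massey / Chien / Forney, errors only (no erasures).
    Raises :class:`QRDecodeError` when the error locator is inconsistent.
    """
    msg = list(codeword)
    n = len(msg)
    # received polynomial R(x) = sum msg[i] * x^(n-1-i); S_j = R(alpha^j)
    synd = [_poly_eval(msg, int(_GF_EXP[j])) for j in range(nsym)]
    if max(synd) == 0:
        return msg[:-nsym]
    # Berlekamp-Massey, locator Lambda lowest-degree-first
    lam = [1]
    prev = [1]
    L = 0
    m = 1
    b = 1
    for i in range(nsym):
        delta = synd[i]
        for k in range(1, L + 1):
            if k < len(lam):
                delta ^= _gf_mul(lam[k], synd[i - k])
        if delta == 0:
            m += 1
        elif 2 * L <= i:
            t = list(lam)
            coef = _gf_mul(delta, _gf_inv(b))
            shift = [0] * m + [_gf_mul(coef, c) for c in prev]
            lam = [a ^ s for a, s in
                   zip(lam + [0] * (len(shift) - len(lam)),
                       shift + [0] * (len(lam) - len(shift)))]
            L = i + 1 - L
            prev = t
            b = delta
            m = 1
        else:
            coef = _gf_mul(delta, _gf_inv(b))
            shift = [0] * m + [_gf_mul(coef, c) for c in prev]
            lam = [a ^ s for a, s in
                   zip(lam + [0] * (len(shift) - len(lam)),
                       shift + [0] * (len(lam) - len(shift)))]
            m += 1
    while len(lam) > 1 and lam[-1] == 0:
        lam.pop()
    nerr = len(lam) - 1
    if nerr != L or 2 * nerr > nsym:
        raise QRDecodeError("too many codeword errors")
    # Chien search: error at list index i <-> polynomial degree e = n-1-i;
    # root of Lambda at X^{-1} = alpha^{-e}
    positions = []
    for i in range(n):
        e = n - 1 - i
        x_inv = int(_GF_EXP[(255 - (e % 255)) % 255])
        if _poly_eval_low(lam, x_inv) == 0:
            positions.append(i)
    if len(positions) != nerr:
        raise QRDecodeError("error locator degree mismatch")
    # Forney with generator roots alpha^0..: e_mag = X * Omega(X^-1)/Lambda'(X^-1)
    omega_full = _poly_mul_low(synd, lam)
    omega = omega_full[:nsym]
    for i in positions:
        e = n - 1 - i
        x = int(_GF_EXP[e % 255])
        x_inv = _gf_inv(x)
        deriv = 0
        for k in range(1, len(lam), 2):
            deriv ^= _gf_mul(lam[k], int(_GF_EXP[((k - 1) * _GF_LOG[x_inv]) % 255]))
        if deriv == 0:
            raise QRDecodeError("Forney derivative is zero")
        mag = _gf_mul(x, _gf_mul(_poly_eval_low(omega, x_inv), _gf_inv(deriv)))
        msg[i] ^= mag
    if any(_poly_eval(msg, int(_GF_EXP[j])) for j in range(nsym)):
        raise QRDecodeError("residual syndrome after correction")
    return msg[:-nsym]


# --------------------------------------------------------------------------
# Code tables (error-correction level M, versions 1-6)
# --------------------------------------------------------------------------

# version -> (ec codewords per block, number of blocks, data codewords per block)
_EC_M = {
    1: (10, 1, 16),
    2: (16, 1, 28),
    3: (26, 1, 44),
    4: (18, 2, 32),
    5: (24, 2, 43),
    6: (16, 4, 27),
}
_ALIGN = {1: [], 2: [6, 18], 3: [6, 22], 4: [6, 26], 5: [6, 30], 6: [6, 34]}
_REMAINDER = {1: 0, 2: 7, 3: 7, 4: 7, 5: 7, 6: 7}

_LEVEL_BITS = {"L": 0b01, "M": 0b00, "Q": 0b11, "H": 0b10}
_FORMAT_MASK = 0b101010000010010
_FORMAT_GEN = 0b10100110111


def _format_bits(level: str, mask: int) -> int:
    data = (_LEVEL_BITS[level] << 3) | mask
    rem = data << 10
    for shift in range(14, 9, -1):
        if rem & (1 << shift):
            rem ^= _FORMAT_GEN << (shift - 10)
    return ((data << 10) | rem) ^ _FORMAT_MASK


# all 32 valid (level, mask) format codewords, for nearest-match decoding
_FORMAT_TABLE = {
    (lvl, m): _format_bits(lvl, m) for lvl in _LEVEL_BITS for m in range(8)
}

_MASKS = [
    lambda i, j: (i + j) % 2 == 0,
    lambda i, j: i % 2 == 0,
    lambda i, j: j % 3 == 0,
    lambda i, j: (i + j) % 3 == 0,
    lambda i, j: (i // 2 + j // 3) % 2 == 0,
    lambda i, j: (i * j) % 2 + (i * j) % 3 == 0,
    lambda i, j: ((i * j) % 2 + (i * j) % 3) % 2 == 0,
    lambda i, j: ((i + j) % 2 + (i * j) % 3) % 2 == 0,
]


def qr_version(n_modules: int) -> int:
    if (n_modules - 17) % 4 or not 1 <= (n_modules - 17) // 4 <= 6:
        raise QRDecodeError(f"unsupported symbol size {n_modules}")
    return (n_modules - 17) // 4


# --------------------------------------------------------------------------
# Module-matrix construction
# --------------------------------------------------------------------------

def _function_mask(version: int) -> np.ndarray:
    """Boolean grid marking function-pattern modules (not data)."""
    n = 17 + 4 * version
    f = np.zeros((n, n), dtype=bool)
    for r0, c0 in [(0, 0), (0, n - 7), (n - 7, 0)]:
        f[max(r0 - 1, 0):r0 + 8, max(c0 - 1, 0):c0 + 8] = True
    f[6, :] = True
    f[:, 6] = True
    centers = _ALIGN[version]
    for rc in centers:
        for cc in centers:
            # skip alignment overlapping finders
            if (rc < 8 and cc < 8) or (rc < 8 and cc > n - 9) or (rc > n - 9 and cc < 8):
                continue
            f[rc - 2:rc + 3, cc - 2:cc + 3] = True
    # format areas + dark module
    f[8, :9] = True
    f[:9, 8] = True
    f[8, n - 8:] = True
    f[n - 8:, 8] = True
    return f


def _place_function_patterns(m: np.ndarray) -> None:
    n = m.shape[0]
    version = qr_version(n)

    def finder(r0, c0):
        for dr in range(-1, 8):
            for dc in range(-1, 8):
                r, c = r0 + dr, c0 + dc
                if not (0 <= r < n and 0 <= c < n):
                    continue
                inside = 0 <= dr <= 6 and 0 <= dc <= 6
                ring = inside and (dr in (0, 6) or dc in (0, 6))
                core = 2 <= dr <= 4 and 2 <= dc <= 4
                m[r, c] = ring or core

    finder(0, 0)
    finder(0, n - 7)
    finder(n - 7, 0)
    for k in range(8, n - 8):
        m[6, k] = k % 2 == 0
        m[k, 6] = k % 2 == 0
    centers = _ALIGN[version]
    for rc in centers:
        for cc in centers:
            if (rc < 8 and cc < 8) or (rc < 8 and cc > n - 9) or (rc > n - 9 and cc < 8):
                continue
            for dr in range(-2, 3):
                for dc in range(-2, 3):
                    m[rc + dr, cc + dc] = max(abs(dr), abs(dc)) != 1
    m[n - 8, 8] = True  # dark module


def _data_coords(version: int) -> list[tuple[int, int]]:
    """Module coordinates in codeword placement order (zigzag, col 6 skipped)."""
    n = 17 + 4 * version
    f = _function_mask(version)
    coords = []
    col = n - 1
    upward = True
    while col > 0:
        if col == 6:
            col -= 1
        rows = range(n - 1, -1, -1) if upward else range(n)
        for r in rows:
            for c in (col, col - 1):
                if not f[r, c]:
                    coords.append((r, c))
        upward = not upward
        col -= 2
    return coords


def _place_format(m: np.ndarray, level: str, mask: int) -> None:
    n = m.shape[0]
    bits = _format_bits(level, mask)
    seq = [(bits >> (14 - i)) & 1 for i in range(15)]
    pos_a = [(8, c) for c in range(6)] + [(8, 7), (8, 8), (7, 8)] + [(r, 8) for r in range(5, -1, -1)]
    pos_b = [(r, 8) for r in range(n - 1, n - 8, -1)] + [(8, c) for c in range(n - 8, n)]
    for (r, c), b in zip(pos_a, seq):
        m[r, c] = bool(b)
    for (r, c), b in zip(pos_b, seq):
        m[r, c] = bool(b)


def _penalty(m: np.ndarray) -> int:
    n = m.shape[0]
    score = 0
    for grid in (m, m.T):
        for line in grid:
            run = 1
            for k in range(1, n):
                if line[k] == line[k - 1]:
                    run += 1
                else:
                    if run >= 5:
                        score += 3 + run - 5
                    run = 1
            if run >= 5:
                score += 3 + run - 5
    blocks = (m[:-1, :-1] == m[1:, :-1]) & (m[:-1, :-1] == m[:-1, 1:]) & (m[:-1, :-1] == m[1:, 1:])
    score += 3 * int(blocks.sum())
    pat = np.array([1, 0, 1, 1, 1, 0, 1, 0, 0, 0, 0], dtype=bool)
    for grid in (m, m.T):
        for line in grid:
            arr = np.asarray(line, dtype=bool)
            for k in range(n - 10):
                win = arr[k:k + 11]
                if np.array_equal(win, pat) or np.array_equal(win, pat[::-1]):
                    score += 40
    dark = int(m.sum())
    ratio = dark * 100 // (n * n)
    score += 10 * (abs(ratio - 50) // 5)
    return score


def encode_text(text: str, min_version: int = 1) -> np.ndarray:
    """Encode ``text`` (byte mode, EC level M) into a boolean module matrix.

    True marks a dark module. The smallest version >= ``min_version`` whose
    level-M byte capacity fits the payload is chosen; mask selection follows
    the standard penalty rules.
    """
    data = text.encode("latin-1", errors="strict")
    version = None
    for v in range(min_version, 7):
        nsym, nblocks, k = _EC_M[v]
        if len(data) <= nblocks * k - 2:
            version = v
            break
    if version is None:
        raise QRCapacityError(
            f"payload of {len(data)} bytes exceeds version-6/M capacity")
    nsym, nblocks, k = _EC_M[version]
    ncw = nblocks * k
    bits = []

    def push(value, width):
        for i in range(width - 1, -1, -1):
            bits.append((value >> i) & 1)

    push(0b0100, 4)
    push(len(data), 8)
    for b in data:
        push(b, 8)
    push(0, min(4, ncw * 8 - len(bits)))
    while len(bits) % 8:
        bits.append(0)
    codewords = [
        int("".join(map(str, bits[i:i + 8])), 2) for i in range(0, len(bits), 8)
    ]
    pad = [0xEC, 0x11]
    while len(codewords) < ncw:
        codewords.append(pad[(len(codewords) - len(bits) // 8) % 2])
    blocks = [codewords[i * k:(i + 1) * k] for i in range(nblocks)]
    ecs = [rs_encode(blk, nsym) for blk in blocks]
    stream = []
    for i in range(k):
        for blk in blocks:
            stream.append(blk[i])
    for i in range(nsym):
        for ec in ecs:
            stream.append(ec[i])
    bitstream = []
    for cw in stream:
        for i in range(7, -1, -1):
            bitstream.append((cw >> i) & 1)
    bitstream.extend([0] * _REMAINDER[version])

    n = 17 + 4 * version
    base = np.zeros((n, n), dtype=bool)
    _place_function_patterns(base)
    coords = _data_coords(version)
    assert len(coords) == len(bitstream)
    best = None
    for mask_id in range(8):
        m = base.copy()
        fn = _MASKS[mask_id]
        for (r, c), b in zip(coords, bitstream):
            m[r, c] = bool(b) ^ fn(r, c)
        _place_format(m, "M", mask_id)
        p = _penalty(m)
        if best is None or p < best[0]:
            best = (p, m)
    return best[1]


# --------------------------------------------------------------------------
# Matrix decoding
# --------------------------------------------------------------------------

def _read_format(m: np.ndarray) -> tuple[str, int]:
    n = m.shape[0]
    pos_a = [(8, c) for c in range(6)] + [(8, 7), (8, 8), (7, 8)] + [(r, 8) for r in range(5, -1, -1)]
    pos_b = [(r, 8) for r in range(n - 1, n - 8, -1)] + [(8, c) for c in range(n - 8, n)]
    best = None
    for positions in (pos_a, pos_b):
        val = 0
        for r, c in positions:
            val = (val << 1) | int(m[r, c])
        for (level, mask), code in _FORMAT_TABLE.items():
            d = bin(val ^ code).count("1")
            if best is None or d < best[0]:
                best = (d, level, mask)
    if best[0] > 3:
        raise QRDecodeError("format information unreadable")
    return best[1], best[2]


def decode_matrix(m: np.ndarray) -> str:
    """Decode a sampled boolean module matrix back to its text payload."""
    m = np.asarray(m, dtype=bool)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise QRDecodeError("module matrix must be square")
    version = qr_version(m.shape[0])
    level, mask_id = _read_format(m)
    if level != "M":
        raise QRDecodeError(f"unsupported error-correction level {level}")
    fn = _MASKS[mask_id]
    coords = _data_coords(version)
    bits = [int(m[r, c]) ^ int(fn(r, c)) for r, c in coords]
    nsym, nblocks, k = _EC_M[version]
    ncw = nblocks * (k + nsym)
    stream = []
    for i in range(ncw):
        byte = 0
        for b in bits[i * 8:(i + 1) * 8]:
            byte = (byte << 1) | b
        stream.append(byte)
    blocks = [[] for _ in range(nblocks)]
    ecs = [[] for _ in range(nblocks)]
    idx = 0
    for i in range(k):
        for b in range(nblocks):
            blocks[b].append(stream[idx])
            idx += 1
    for i in range(nsym):
        for b in range(nblocks):
            ecs[b].append(stream[idx])
            idx += 1
    data = []
    for blk, ec in zip(blocks, ecs):
        data.extend(rs_decode(blk + ec, nsym))
    # parse byte-mode segment
    bitpos = 0

    def take(width):
        nonlocal bitpos
        val = 0
        for _ in range(width):
            byte = data[bitpos // 8]
            val = (val << 1) | ((byte >> (7 - bitpos % 8)) & 1)
            bitpos += 1
        return val

    mode = take(4)
    if mode != 0b0100:
        raise QRDecodeError(f"unsupported mode indicator {mode:04b}")
    count = take(8)
    if count * 8 > (len(data) * 8 - bitpos):
        raise QRDecodeError("corrupt character count")
    payload = bytes(take(8) for _ in range(count))
    return payload.decode("latin-1")


# --------------------------------------------------------------------------
# Image decoding (finder location + grid sampling)
# --------------------------------------------------------------------------

def _finder_candidates(dark: np.ndarray) -> list[tuple[float, float, float]]:
    """Scanline search for 1:1:3:1:1 finder patterns.

    Returns candidate (row, col, module_size) triples, clustered.
    """
    h, w = dark.shape
    raw = []
    for r in range(h):
        line = dark[r]
        # run-length encode the row
        change = np.flatnonzero(np.diff(line.astype(np.int8)))
        bounds = np.concatenate(([0], change + 1, [w]))
        lengths = np.diff(bounds)
        starts = bounds[:-1]
        vals = line[starts]
        for i in range(len(lengths) - 4):
            if not vals[i]:
                continue
            seg = lengths[i:i + 5].astype(float)
            module = seg.sum() / 7.0
            if module < 1.0:
                continue
            expect = np.array([1, 1, 3, 1, 1]) * module
            if np.all(np.abs(seg - expect) <= 0.75 * module + 0.5):
                cc = starts[i] + seg[0] + seg[1] + seg[2] / 2.0
                raw.append((r, cc, module))
    # vertical confirmation: the column through the center must also show 1:1:3:1:1
    confirmed = []
    for r, cc, module in raw:
        c = int(round(cc))
        if not 0 <= c < w:
            continue
        col = dark[:, c]
        up = r
        while up > 0 and col[up - 1] == col[r]:
            up -= 1
        down = r
        while down < h - 1 and col[down + 1] == col[r]:
            down += 1
        center_len = down - up + 1
        if not col[r] or not (1.5 * module <= center_len <= 4.5 * module):
            continue
        confirmed.append(((up + down) / 2.0, cc, module))
    # cluster by proximity
    clusters: list[list[tuple[float, float, float]]] = []
    for cand in confirmed:
        for cl in clusters:
            r0, c0, m0 = cl[0]
            if abs(cand[0] - r0) < 3 * m0 and abs(cand[1] - c0) < 3 * m0:
                cl.append(cand)
                break
        else:
            clusters.append([cand])
    clusters.sort(key=len, reverse=True)
    out = []
    for cl in clusters[:8]:  # strongest clusters only; keeps the search tractable
        arr = np.array(cl)
        out.append((float(np.median(arr[:, 0])), float(np.median(arr[:, 1])),
                    float(np.median(arr[:, 2]))))
    return out


def _orient_finders(cands):
    """Pick 3 finder centers and order them (top-left, top-right, bottom-left)."""
    if len(cands) < 3:
        raise QRDecodeError("fewer than three finder patterns found")
    best = None
    from itertools import combinations, permutations
    for triple in combinations(cands, 3):
        for tl, a, b in permutations(triple):
            v1 = np.array([a[0] - tl[0], a[1] - tl[1]])
            v2 = np.array([b[0] - tl[0], b[1] - tl[1]])
            l1, l2 = np.linalg.norm(v1), np.linalg.norm(v2)
            if l1 < 1e-6 or l2 < 1e-6:
                continue
            cosang = abs(v1 @ v2) / (l1 * l2)
            asym = abs(l1 - l2) / max(l1, l2)
            score = cosang + asym
            if best is None or score < best[0]:
                best = (score, tl, a, b)
    if best is None or best[0] > 0.45:
        raise QRDecodeError("finder geometry inconsistent")
    _, tl, a, b = best
    # right-handed orientation (row axis down, col axis right): for a
    # non-mirrored code, cross(v_tr, v_bl) in (row, col) coords is positive
    v1 = np.array([a[0] - tl[0], a[1] - tl[1]])
    v2 = np.array([b[0] - tl[0], b[1] - tl[1]])
    if v1[0] * v2[1] - v1[1] * v2[0] > 0:
        a, b = b, a
    return tl, a, b


def _sample_grid(dark: np.ndarray, tl, tr, bl) -> np.ndarray:
    module = np.mean([tl[2], tr[2], bl[2]])
    dist = np.linalg.norm([tr[0] - tl[0], tr[1] - tl[1]])
    n = int(round(dist / module)) + 7
    n = 17 + 4 * int(np.clip(round((n - 17) / 4), 1, 6))
    span = n - 7
    ux = np.array([(tr[0] - tl[0]) / span, (tr[1] - tl[1]) / span])
    uy = np.array([(bl[0] - tl[0]) / span, (bl[1] - tl[1]) / span])
    origin = np.array([tl[0], tl[1]]) - 3 * ux - 3 * uy
    ii, jj = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    rows = origin[0] + jj * ux[0] + ii * uy[0]
    cols = origin[1] + jj * ux[1] + ii * uy[1]
    h, w = dark.shape
    if rows.min() < -2 or rows.max() > h + 1 or cols.min() < -2 or cols.max() > w + 1:
        raise QRDecodeError("sampled grid leaves the image")
    # majority vote over a small neighborhood around each module center
    votes = np.zeros((n, n), dtype=np.int32)
    total = 0
    rad = max(1, int(module / 4))
    offs = range(-rad, rad + 1)
    for dr in offs:
        for dc in offs:
            r = np.clip(np.round(rows + dr).astype(int), 0, h - 1)
            c = np.clip(np.round(cols + dc).astype(int), 0, w - 1)
            votes += dark[r, c]
            total += 1
    return votes * 2 > total


def decode_image(gray: np.ndarray, binarize: str = "otsu") -> str:
    """Decode a QR symbol from a 2D grayscale image.

    ``binarize`` selects the thresholding backend: ``"otsu"`` (global) or
    ``"adaptive"`` (local-mean). Dark pixels are taken as QR modules, as in a
    printed code; MR slices of the phantoms satisfy this in any weighting
    because plastic is signal-poor. Raises :class:`QRDecodeError` on failure.
    """
    img = np.asarray(gray, dtype=float)
    if img.ndim != 2:
        raise QRDecodeError("expected a 2D image")
    if img.max() == img.min():
        raise QRDecodeError("blank image")
    if binarize == "otsu":
        from skimage.filters import threshold_otsu
        thresh = threshold_otsu(img)
        dark = img < thresh
    elif binarize == "adaptive":
        from scipy.ndimage import gaussian_filter, uniform_filter
        smoothed = gaussian_filter(img, sigma=1.0)
        size = max(15, min(img.shape) // 8) | 1
        local = uniform_filter(smoothed, size=size, mode="nearest")
        dark = smoothed < local - 0.05 * (img.max() - img.min())
    else:
        raise ValueError(f"unknown binarizer {binarize!r}")
    cands = _finder_candidates(dark)
    tl, tr, bl = _orient_finders(cands)
    mods = _sample_grid(dark, tl, tr, bl)
    try:
        return decode_matrix(mods)
    except QRDecodeError:
        # mirrored rendering: transpose swaps the reading order
        return decode_matrix(mods.T)


def render_matrix(m: np.ndarray, module_px: int = 8, quiet: int = 4) -> np.ndarray:
    """Render a module matrix as an 8-bit grayscale image (dark=0, light=255)."""
    m = np.asarray(m, dtype=bool)
    n = m.shape[0]
    img = np.ones((n + 2 * quiet, n + 2 * quiet), dtype=np.uint8) * 255
    img[quiet:quiet + n, quiet:quiet + n] = np.where(m, 0, 255)
    return np.kron(img, np.ones((module_px, module_px), dtype=np.uint8))
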