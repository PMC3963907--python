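"""Standard colorimetric reference tables.

CIE 1931 2-degree standard-observer colour-matching functions and the CIE
D65 illuminant relative spectral power distribution, both on a 10 nm grid
over 380-730 nm.  The truncated red/near-IR tail (740-780 nm) contributes
< 0.1 % to any tristimulus integral and is omitted.  Values are the
published standard constants.
"""

import numpy as np

# wavelength (nm), x_bar, y_bar, z_bar, D65 relative SPD
_TABLE = np.array([
    [380, 0.0014, 0.0000, 0.0065, 49.98],
    [390, 0.0042, 0.0001, 0.0201, 54.65],
    [400, 0.0143, 0.0004, 0.0679, 82.75],
    [410, 0.0435, 0.0012, 0.2074, 91.49],
    [420, 0.1344, 0.0040, 0.6456, 93.43],
    [430, 0.2839, 0.0116, 1.3856, 86.68],
    [440, 0.3483, 0.0230, 1.7471, 104.86],
    [450, 0.3362, 0.0380, 1.7721, 117.01],
    [460, 0.2908, 0.0600, 1.6692, 117.81],
    [470, 0.1954, 0.0910, 1.2876, 114.86],
    [480, 0.0956, 0.1390, 0.8130, 115.92],
    [490, 0.0320, 0.2080, 0.4652, 108.81],
    [500, 0.0049, 0.3230, 0.2720, 109.35],
    [510, 0.0093, 0.5030, 0.1582, 107.80],
    [520, 0.0633, 0.7100, 0.0782, 104.79],
    [530, 0.1655, 0.8620, 0.0422, 107.69],
    [540, 0.2904, 0.9540, 0.0203, 104.41],
    [550, 0.4334, 0.9950, 0.0087, 104.05],
    [560, 0.5945, 0.9950, 0.0039, 100.00],
    [570, 0.7621, 0.9520, 0.0021, 96.33],
    [580, 0.9163, 0.8700, 0.0017, 95.79],
    [590, 1.0263, 0.7570, 0.0011, 88.69],
    [600, 1.0622, 0.6310, 0.0008, 90.01],
    [610, 1.0026, 0.5030, 0.0003, 89.60],
    [620, 0.8544, 0.3810, 0.0002, 87.70],
    [630, 0.6424, 0.2650, 0.0000, 83.29],
    [640, 0.4479, 0.1750, 0.0000, 83.70],
    [650, 0.2835, 0.1070, 0.0000, 80.03],
    [660, 0.1649, 0.0610, 0.0000, 80.21],
    [670, 0.0874, 0.0320, 0.0000, 82.28],
    [680, 0.0468, 0.0170, 0.0000, 78.28],
    [690, 0.0227, 0.0082, 0.0000, 69.72],
    [700, 0.0114, 0.0041, 0.0000, 71.61],
    [710, 0.0058, 0.0021, 0.0000, 74.35],
    [720, 0.0029, 0.0010, 0.0000, 61.60],
    [730, 0.0014, 0.0005, 0.0000, 69.89],
])

WAVELENGTHS = _TABLE[:, 0]
XBAR = _TABLE[:, 1]
YBAR = _TABLE[:, 2]
ZBAR = _TABLE[:, 3]
D65 = _TABLE[:, 4]
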