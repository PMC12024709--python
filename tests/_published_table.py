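"""Frozen reference grid for the 240.80 mm phantom, reference C3.

Per (electrode, depth): (x_mm, y_mm, z_mm, distance_mm, delta_v_mV,
ef_mV_per_mm); delta_v is None at the not-recordable pad sites.
The sixth electrode of the source table is mislabelled; its
coordinates (70.77, 70.77, 0.00) identify it as Fz and it is
stored under that name.
"""

PUBLISHED = {
    "Fp1": {
        "Z0": (35.38, 108.9, -60.2, 129.37, 15800.0, 122.13),
        "Z33": (58.97, 36.3, -85.0, 109.64, 41200.0, 375.77),
        "Z66": (58.97, -36.3, -109.81, 129.82, 48400.0, 372.82),
        "Z100": (35.38, -108.9, -134.61, 176.73, 53200.0, 301.03),
    },
    "Fpz": {
        "Z0": (70.77, 114.51, -60.2, 147.46, 8080.0, 54.79),
        "Z33": (70.77, 38.17, -85.0, 117.01, 15600.0, 133.32),
        "Z66": (70.77, -38.17, -109.81, 136.1, 41600.0, 305.66),
        "Z100": (70.77, -114.51, -134.61, 190.37, 16600.0, 87.2),
    },
    "Fp2": {
        "Z0": (106.15, 108.9, -60.2, 163.56, 39600.0, 242.11),
        "Z33": (82.56, 36.3, -85.0, 123.94, 42800.0, 345.34),
        "Z66": (82.56, -36.3, -109.81, 142.1, 50400.0, 354.68),
        "Z100": (106.15, -108.9, -134.61, 203.1, 42400.0, 208.77),
    },
    "F7": {
        "Z0": (-21.87, 67.31, -60.2, 92.91, 39200.0, 421.91),
        "Z33": (39.89, 22.44, -85.0, 96.54, 40800.0, 422.62),
        "Z66": (39.89, -22.44, -109.81, 118.96, 44000.0, 369.86),
        "Z100": (-21.87, -67.31, -134.61, 152.08, 42400.0, 278.8),
    },
    "F3": {
        "Z0": (13.52, 78.8, -26.64, 84.27, 35600.0, 484.73),
        "Z33": (51.68, 26.27, -73.82, 93.86, 39600.0, 436.23),
        "Z66": (51.68, -26.27, -121.0, 134.17, 40400.0, 291.43),
        "Z100": (13.52, -78.8, -168.17, 186.21, 54000.0, 275.85),
    },
    "Fz": {
        "Z0": (70.77, 70.77, 0.0, 100.08, 32000.0, 319.73),
        "Z33": (70.77, 23.59, -64.94, 98.9, 34400.0, 347.82),
        "Z66": (70.77, -23.59, -129.87, 149.77, 44000.0, 293.78),
        "Z100": (70.77, -70.77, -194.81, 219.02, 49600.0, 226.47),
    },
    "F4": {
        "Z0": (128.02, 78.8, -26.64, 152.67, 29200.0, 208.24),
        "Z33": (89.85, 26.27, -73.82, 119.22, 33600.0, 294.73),
        "Z66": (89.85, -26.27, -121.0, 152.98, 44400.0, 286.76),
        "Z100": (128.02, -78.8, -168.17, 225.57, 51600.0, 225.01),
    },
    "F8": {
        "Z0": (163.41, 67.31, -60.2, 186.7, 31600.0, 169.26),
        "Z33": (101.65, 22.44, -85.0, 134.39, 35600.0, 264.9),
        "Z66": (101.65, -22.44, -109.81, 151.31, 42800.0, 282.87),
        "Z100": (163.41, -67.31, -134.61, 222.15, 47600.0, 214.27),
    },
    "T3": {
        "Z0": (-43.74, 0.0, -60.2, 74.41, 30800.0, 413.92),
        "Z33": (32.6, 0.0, -85.0, 91.04, 32000.0, 351.49),
        "Z66": (32.6, -0.0, -109.81, 114.54, 35200.0, 307.3),
        "Z100": (-43.74, -0.0, -134.61, 141.54, 36800.0, 260.0),
    },
    "C3": {
        "Z0": (-0.0, 0.0, 0.0, 0.0, None, 404.08),
        "Z33": (47.18, 0.0, -64.94, 80.27, None, 436.54),
        "Z66": (47.18, -0.0, -129.87, 138.18, None, 275.59),
        "Z100": (-0.0, -0.0, -194.81, 194.81, None, 219.7),
    },
    "Cz": {
        "Z0": (70.77, 0.0, 22.99, 74.41, 28000.0, 376.29),
        "Z33": (70.77, 0.0, -57.27, 91.04, 33200.0, 364.67),
        "Z66": (70.77, 0.0, -137.54, 154.68, 43600.0, 281.88),
        "Z100": (70.77, 0.0, -217.81, 229.01, 52000.0, 227.06),
    },
    "C4": {
        "Z0": (141.54, 0.0, 0.0, 141.54, None, 0.0),
        "Z33": (94.36, 0.0, -64.94, 114.54, None, 267.49),
        "Z66": (94.36, 0.0, -129.87, 160.53, None, 229.73),
        "Z100": (141.54, 0.0, -194.81, 240.8, None, 170.76),
    },
    "T4": {
        "Z0": (185.28, 0.0, -60.2, 194.81, 29200.0, 149.89),
        "Z33": (108.94, 0.0, -85.0, 138.18, 32000.0, 231.59),
        "Z66": (108.94, 0.0, -109.81, 154.68, 36800.0, 237.91),
        "Z100": (185.28, 0.0, -134.61, 229.01, 38000.0, 165.93),
    },
    "T5": {
        "Z0": (-21.87, -67.31, -60.2, 92.91, 29600.0, 318.59),
        "Z33": (39.89, -22.44, -85.0, 96.54, 32800.0, 339.75),
        "Z66": (39.89, 22.44, -109.81, 118.96, 34800.0, 292.53),
        "Z100": (-21.87, 67.31, -134.61, 152.08, 37600.0, 247.24),
    },
    "P3": {
        "Z0": (13.52, -78.8, -26.64, 84.27, 28000.0, 381.25),
        "Z33": (51.68, -26.27, -73.82, 93.86, 30000.0, 330.48),
        "Z66": (51.68, 26.27, -121.0, 134.17, 36000.0, 259.69),
        "Z100": (13.52, 78.8, -168.17, 186.21, 43200.0, 220.68),
    },
    "Pz": {
        "Z0": (70.77, -70.77, 0.0, 100.08, 24400.0, 243.8),
        "Z33": (70.77, -23.59, -64.94, 98.9, 27600.0, 279.06),
        "Z66": (70.77, 23.59, -129.87, 149.77, 34400.0, 229.68),
        "Z100": (70.77, 70.77, -194.81, 219.02, 36700.0, 167.57),
    },
    "P4": {
        "Z0": (128.02, -78.8, -26.64, 152.67, 24000.0, 171.16),
        "Z33": (89.85, -26.27, -73.82, 119.22, 27200.0, 238.59),
        "Z66": (89.85, 26.27, -121.0, 152.98, 32400.0, 209.26),
        "Z100": (128.02, 78.8, -168.17, 225.57, 36800.0, 160.47),
    },
    "T6": {
        "Z0": (163.41, -67.31, -60.2, 186.7, 21600.0, 115.69),
        "Z33": (101.65, -22.44, -85.0, 134.39, 24800.0, 184.53),
        "Z66": (101.65, 22.44, -109.81, 151.31, 28000.0, 185.06),
        "Z100": (163.41, 67.31, -134.61, 222.15, 31600.0, 142.24),
    },
    "O1": {
        "Z0": (35.38, -108.9, -60.2, 129.37, 26400.0, 204.07),
        "Z33": (58.97, -36.3, -85.0, 109.64, 28800.0, 262.67),
        "Z66": (58.97, 36.3, -109.81, 129.82, 33200.0, 255.74),
        "Z100": (35.38, 108.9, -134.61, 176.73, 33200.0, 187.86),
    },
    "Oz": {
        "Z0": (70.77, -114.51, -60.2, 147.46, 22800.0, 154.62),
        "Z33": (70.77, -38.17, -85.0, 117.01, 25200.0, 215.37),
        "Z66": (70.77, 38.17, -109.81, 136.1, 29200.0, 214.55),
        "Z100": (70.77, 114.51, -134.61, 190.37, 33200.0, 174.4),
    },
    "O2": {
        "Z0": (106.15, -108.9, -60.2, 163.56, 22000.0, 134.51),
        "Z33": (82.56, -36.3, -85.0, 123.94, 24400.0, 196.88),
        "Z66": (82.56, 36.3, -109.81, 142.1, 28800.0, 202.68),
        "Z100": (106.15, 108.9, -134.61, 203.1, 34800.0, 171.35),
    },
}

# rows whose printed EF disagrees with their own printed dV / distance
# (documented transcription inconsistencies, excluded from numeric checks)
EF_INCONSISTENT = frozenset(
    [(e, d) for e in ("F3", "F4", "P3", "P4")
     for d in ("Z0", "Z33", "Z66", "Z100")]
    + [("C4", "Z0")]
)
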