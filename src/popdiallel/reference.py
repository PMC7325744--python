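"""Reference combining-ability estimates used as consistency fixtures.

A published 4-maternal x 12-paternal quality-protein popcorn diallel
reported per-trait maternal and paternal GCA columns; because GCA effects
are deviations from a grand mean, every column must sum to zero up to
rounding of the printed values. The tables are kept here as fixed inputs
for zero-sum consistency checks; they are not used by any estimator.
"""

from __future__ import annotations

REFERENCE_TRAITS = (
    "germination",
    "dap",
    "rot",
    "neh",
    "el",
    "rpe",
    "weg",
    "ks",
    "vit",
    "hgw",
    "ev",
    "pa",
)

#: maternal parent id -> GCA value per trait (column order REFERENCE_TRAITS)
REFERENCE_MGCA: dict[str, tuple[float, ...]] = {
    "I05": (0.012, 0.915, 0.020, -0.653, -1.419, -0.680, -9.033, 7.407,
            0.110, -1.030, 25.788, 0.002),
    "I06": (0.114, 0.647, 0.064, 0.635, -1.715, -0.897, -10.186, 6.089,
            0.055, -0.764, 30.836, 0.006),
    "I09": (-0.038, -0.708, -0.075, 0.374, 1.950, 0.465, 11.841, -7.732,
            -0.048, 1.084, -35.859, -0.010),
    "I10": (-0.088, -0.854, -0.010, -0.356, 1.184, 1.112, 7.378, -5.764,
            -0.118, 0.709, -20.765, 0.003),
}

#: paternal parent id -> GCA value per trait (column order REFERENCE_TRAITS)
REFERENCE_PGCA: dict[str, tuple[float, ...]] = {
    "I01": (0.048, 0.220, 0.000, 0.519, -1.283, -1.235, -3.867, -0.135,
            -0.148, 0.051, 18.245, -0.009),
    "I02": (-0.122, 1.554, 0.000, -1.293, -0.334, -0.776, -5.470, 2.646,
            -0.315, -0.258, 4.426, -0.008),
    "I03": (0.013, -0.914, 0.000, 0.208, -0.215, 0.658, 2.234, -1.423,
            -0.682, 0.074, -25.857, 0.001),
    "I04": (0.010, 0.736, 0.000, 0.070, -1.066, 0.837, 1.537, 0.669,
            -0.281, -0.134, -28.950, -0.005),
    "I05": (-0.006, -0.139, 0.000, -0.150, -0.023, -0.982, -4.466, 5.214,
            0.798, -0.519, 53.808, 0.014),
    "I06": (-0.050, 0.300, 0.000, -0.499, -0.042, -0.888, -4.474, 4.136,
            0.698, -0.500, 72.878, 0.018),
    "I07": (-0.131, 0.674, 0.000, -1.689, 0.401, 0.267, 3.179, -6.910,
            -0.404, 0.989, -26.492, 0.004),
    "I08": (0.048, 1.105, 0.000, 0.346, -0.611, -0.307, -4.625, 5.485,
            -0.266, -0.765, 25.927, 0.003),
    "I09": (0.039, -1.315, 0.000, 0.697, 1.330, 0.561, 4.611, -2.976,
            0.578, 0.297, 9.362, 0.009),
    "I10": (0.023, -1.126, 0.000, 0.306, 1.670, 0.523, 2.197, -0.583,
            0.494, 0.027, 33.080, 0.020),
    "I11": (0.075, -0.688, 0.000, 0.795, -0.343, 0.920, 3.512, -1.237,
            -0.531, 0.067, -57.287, -0.009),
    # ks carries -4.887: the printed value lost its minus sign (the column
    # must sum to zero; restoring the sign gives -0.001, all others ~0.000)
    "I12": (0.054, -0.407, 0.000, 0.691, 0.515, 0.422, 5.632, -4.887,
            0.059, 0.671, -79.139, -0.039),
}


def column_sums(table: dict[str, tuple[float, ...]]) -> dict[str, float]:
    """Per-trait column sum of a reference GCA table."""
    return {
        trait: sum(row[i] for row in table.values())
        for i, trait in enumerate(REFERENCE_TRAITS)
    }
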