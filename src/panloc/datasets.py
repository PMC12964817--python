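"""Small built-in datasets for worked examples.

The breed panel below is the published distribution of cattle assemblies
carrying the ~7 kb alternative path upstream of *KIT*, one row per breed:
how many assemblies of that breed entered the pangenome and how many of
them showed the alternative path. White-headed breeds are starred in the
original table; here they carry ``phenotype == "white"``.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["kit_sv_breed_panel", "breed_panel_assemblies"]

# (breed, n assemblies, n carrying the alternative path, head phenotype)
_BREED_PANEL = [
    ("Abondance", 5, 3, "white"),
    ("Hereford", 1, 1, "white"),
    ("Montbeliarde", 6, 5, "white"),
    ("Normande", 8, 7, "white"),
    ("Simmental", 6, 5, "white"),
    ("Aubrac", 7, 0, "colored"),
    ("Blonde d'Aquitaine", 4, 0, "colored"),
    ("Brown Swiss", 7, 0, "colored"),
    ("Charolaise", 4, 0, "colored"),
    ("Evolener", 1, 0, "colored"),
    ("Highland", 1, 0, "colored"),
    ("Holstein", 9, 0, "colored"),
    ("Limousine", 2, 0, "colored"),
    ("Parthenaise", 3, 0, "colored"),
    ("Rouge Flamande", 2, 0, "colored"),
    ("Tarentaise", 5, 0, "colored"),
    ("Vosgienne", 4, 0, "colored"),
    ("Yak", 1, 0, "colored"),
]


def kit_sv_breed_panel() -> pd.DataFrame:
    """Per-breed assembly counts: breed, n_assemblies, n_carriers, phenotype."""
    return pd.DataFrame(
        _BREED_PANEL, columns=["breed", "n_assemblies", "n_carriers", "phenotype"]
    )


def breed_panel_assemblies() -> tuple[dict[str, bool], pd.DataFrame]:
    """Expand the panel to one row per assembly.

    Returns ``(carriers, phenotypes)`` in the shapes
    :func:`panloc.association.breed_carrier_summary` consumes: a carrier
    flag per assembly and a phenotype table with sample/breed/phenotype
    columns. Assembly names are synthetic (``<breed>_<i>``); which
    assemblies of a breed carry the path is arbitrary, only the counts are
    data.
    """
    carriers: dict[str, bool] = {}
    rows = []
    for breed, n, k, phenotype in _BREED_PANEL:
        for i in range(n):
            name = f"{breed.replace(' ', '')}_{i + 1}"
            carriers[name] = i < k
            rows.append({"sample": name, "breed": breed, "phenotype": phenotype})
    return carriers, pd.DataFrame(rows)
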