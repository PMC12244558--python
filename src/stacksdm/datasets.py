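"""Bundled reference tables.

``synthetic_gulf_census`` expands the published order-, genus- and
wall-type tallies of a basin-wide compilation of Arabian Gulf benthic
foraminifera (492 modelled species) into a synthetic species-level
census: species names are placeholders, but the group counts match the
published tallies, so composition summaries computed from it reproduce
the published percentage shares. Wall types are assigned to match the
published wall-type tallies (hyaline 288, porcelaneous 142, agglutinated
62); because the published order-level and wall-type tallies are not
mutually consistent, a few non-miliolid placeholders carry agglutinated
walls to close the books.
"""

from __future__ import annotations

import pandas as pd

#: species count per order in the compiled assemblage
ORDER_COUNTS: dict[str, int] = {
    "Rotaliida": 270,
    "Miliolida": 142,
    "Lituolida": 32,
    "Textulariida": 22,
    "Nodosariida": 11,
    "Polymorphinida": 11,
    "Spirillinida": 2,
    "Astrorhizida": 1,
    "Robertinida": 1,
}

#: species count of the most diverse genera (genus -> (order, count))
GENUS_COUNTS: dict[str, tuple[str, int]] = {
    "Quinqueloculina": ("Miliolida", 69),
    "Triloculina": ("Miliolida", 26),
    "Spiroloculina": ("Miliolida", 22),
    "Elphidium": ("Rotaliida", 20),
    "Ammonia": ("Rotaliida", 15),
    "Bolivina": ("Rotaliida", 14),
}

#: species count per test wall type
WALL_COUNTS: dict[str, int] = {
    "hyaline": 288,
    "porcelaneous": 142,
    "agglutinated": 62,
}

TOTAL_SPECIES = 492


def synthetic_gulf_census() -> tuple[pd.DataFrame, pd.DataFrame]:
    """Synthetic species-level census matching the published group tallies.

    Returns ``(records, taxonomy)``: a one-record-per-species occurrence
    table and a taxonomy table with order, genus, family, superfamily and
    wall type per species. Placeholder genera/families absorb the species
    not belonging to a named genus.
    """
    rows = []
    remaining_by_order = dict(ORDER_COUNTS)
    for genus, (order, count) in GENUS_COUNTS.items():
        for i in range(count):
            rows.append({"genus": genus, "order": order})
        remaining_by_order[order] -= count
    for order, count in remaining_by_order.items():
        if count < 0:
            raise AssertionError(f"genus counts exceed order count for {order}")
        for i in range(count):
            rows.append({"genus": f"{order}genus{i % 40:02d}", "order": order})
    assert len(rows) == TOTAL_SPECIES

    # porcelaneous = Miliolida; agglutinated fills from the agglutinated
    # orders then non-miliolid placeholders; the rest are hyaline
    agglutinated_orders = {"Lituolida", "Textulariida", "Astrorhizida"}
    n_aggl = WALL_COUNTS["agglutinated"]
    taxonomy_rows = []
    aggl_assigned = sum(
        1 for r in rows if r["order"] in agglutinated_orders
    )
    extra_aggl_needed = n_aggl - aggl_assigned
    for i, r in enumerate(rows):
        order, genus = r["order"], r["genus"]
        if order == "Miliolida":
            wall = "porcelaneous"
        elif order in agglutinated_orders:
            wall = "agglutinated"
        elif extra_aggl_needed > 0 and genus.startswith("Rotaliidagenus"):
            wall = "agglutinated"
            extra_aggl_needed -= 1
        else:
            wall = "hyaline"
        species = f"{genus[0].upper()}{genus[1:]} taxon{i:03d}"
        taxonomy_rows.append(
            {
                "species": species,
                "genus": genus,
                "family": f"{order}_family{sum(map(ord, genus)) % 10:02d}",
                "superfamily": f"{order}_superfamily{sum(map(ord, genus)) % 5:02d}",
                "order": order,
                "wall_type": wall,
            }
        )
    taxonomy = pd.DataFrame(taxonomy_rows)
    counts = taxonomy["wall_type"].value_counts().to_dict()
    assert counts == WALL_COUNTS, counts
    records = pd.DataFrame(
        {
            "taxon": taxonomy["species"],
            "lon": 51.0,
            "lat": 26.0,
            "depth_m": -20.0,
            "source_id": "census",
        }
    )
    return records, taxonomy
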