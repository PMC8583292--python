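"""Published national assessment summary used as worked-example inputs.

Class totals per ecosystem from the published Romanian national
ecosystem-degradation assessment (natural / semi-degraded / degraded, in
each ecosystem's native unit: km² for areal ecosystems, km for rivers,
cave counts). They serve as inputs to the reporting worked examples; the
percentage shares are recomputed from them, never stored.

A few printed percentage cells of the source summary are internally
inconsistent with their own class totals (the river and coastal degraded
shares, and the cave degraded share by one unit in the last decimal);
:data:`CONSISTENT_CELLS` lists the (kind, class) pairs whose printed share
agrees with the printed totals, which is the surface the worked examples
reproduce.
"""

from .features import DEGRADED, NATURAL, SEMI_DEGRADED

#: kind -> (unit, {class: total}, grand total)
PUBLISHED_CLASS_TOTALS = {
    "forest": ("km2", {NATURAL: 63651.34, SEMI_DEGRADED: 2115.27, DEGRADED: 6124.23},
               71890.84),
    "grassland": ("km2", {NATURAL: 7080.05, SEMI_DEGRADED: 12790.72, DEGRADED: 12486.37},
                  32357.14),
    "cave": ("count", {NATURAL: 15, SEMI_DEGRADED: 315, DEGRADED: 9}, 339),
    "lake": ("km2", {NATURAL: 410.95, SEMI_DEGRADED: 1521.41, DEGRADED: 315.91},
             2248.28),
    "river": ("km", {NATURAL: 16320.52, SEMI_DEGRADED: 44508.82, DEGRADED: 2238.82},
              84068.17),
    "coastal": ("km2", {NATURAL: 42.5, SEMI_DEGRADED: 1362.32, DEGRADED: 169.17}, 1574.0),
}

#: Printed percentage cells that are internally consistent with the totals.
CONSISTENT_CELLS = {
    ("forest", NATURAL): 88.54,
    ("forest", SEMI_DEGRADED): 2.94,
    ("forest", DEGRADED): 8.52,
    ("grassland", NATURAL): 21.88,
    ("grassland", SEMI_DEGRADED): 39.53,
    ("grassland", DEGRADED): 38.59,
    ("cave", NATURAL): 4.42,
    ("cave", SEMI_DEGRADED): 92.92,
    ("lake", NATURAL): 18.28,
    ("lake", SEMI_DEGRADED): 67.67,
    ("lake", DEGRADED): 14.05,
    ("river", NATURAL): 19.41,
    ("river", SEMI_DEGRADED): 52.94,
    ("coastal", NATURAL): 2.70,
    ("coastal", SEMI_DEGRADED): 86.55,
}
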