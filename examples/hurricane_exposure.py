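"""Which watersheds a hurricane affected, and at what category.

Writes a small HURDAT2-format archive, parses it back, buffers each
track point by its storm diameter (2x the largest 34-kt wind radius,
with category-average fallback) and intersects the buffers with
watershed polygons per epoch.
"""

from shapely.geometry import Polygon

import marshchange as mc

katrina_like = mc.TrackSpec("AL", 12, 2005, "DEMO", points=[
    ("20050828 1200", 27.2, -89.2, 145, (120, 120, 75, 100)),
    ("20050829 1200", 29.5, -89.6, 110, (120, 120, 80, 100)),
    ("20050830 0000", 32.6, -89.1, 50, None),
])
text = mc.generate_hurdat([katrina_like])
tracks = mc.parse_hurdat2(text)
print(f"parsed {len(tracks)} storm(s), "
      f"{len(tracks[0].points)} points, peak category "
      f"{max(mc.saffir_simpson(w) for w in tracks[0].points.max_wind_kt)}")

watersheds = {
    1: Polygon([(-90.5, 29), (-89, 29), (-89, 30.5), (-90.5, 30.5)]),  # hit
    2: Polygon([(-84, 29), (-82.5, 29), (-82.5, 30.5), (-84, 30.5)]),  # far east
}
exposure = mc.watershed_exposure(tracks, watersheds, mc.default_epochs())
print(exposure[exposure.landfall | (exposure.epoch == "2005-2009")])
# category is the highest Saffir-Simpson category among buffer-intersecting
# hurricane-strength points in the epoch; 0 means no exposure.
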