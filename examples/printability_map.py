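"""Printable region of the temperature–pressure plane for pure PCL.

A cell prints well when the extrusion velocity reaches 0.21 mm/s (slower
extrusion lays wavy lines) and the strut diameter stays at or under the
700 um strut pitch (wider struts close the scaffold pores).  Along each
temperature row the printable set is one contiguous pressure band: entered
through the velocity line, left through the pitch line.
"""

from strutcast import ProcessGrid, default_blends, default_geometry, sweep

grid = ProcessGrid(
    T_values=(120.0, 125.0, 130.0, 135.0, 140.0),
    P_values=tuple(float(p) for p in range(150_000, 600_001, 50_000)),
)
pmap = sweep(default_blends()["pcl"], default_geometry(), grid)

symbols = {"too_slow": ".", "ok": "#", "too_wide": "x", "failed": "!"}
nP = len(grid.P_values)
print("P (kPa):" + "".join(f"{int(p/1e3):5d}" for p in grid.P_values))
for i, T in enumerate(grid.T_values):
    row = pmap.cells[i * nP : (i + 1) * nP]
    print(f"{T:5.0f} C " + "".join(f"{symbols[c.limiting_criterion]:>5}" for c in row))
n_ok = sum(c.printable for c in pmap.cells)
print(f"\n# printable, . too slow (v < 0.21 mm/s), x too wide (d > 700 um)")
print(f"{n_ok}/{len(pmap.cells)} cells printable: the band climbs to lower")
print("pressures as temperature rises, because the melt thins (WLF) and the")
print("same pressure extrudes faster — until the strut outgrows the pitch.")
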