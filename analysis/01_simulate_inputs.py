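"""Generate the synthetic study dataset all downstream analyses consume.

Writes, under results/data/: the amyloid-stain image, the transcript table
with two plaque-enriched genes (fold 5, the late-disease condition) and one
homogeneous control, the segmented-cell MTX trio with a plaque-adjacent
T-cell type and a uniform microglia type, paired DAPI/T-cell images, and
the ground-truth manifests that score every later stage.

Run:  python analysis/01_simulate_inputs.py [--seed 0]
"""
import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

import plaqueniche as pn
from plaqueniche import io

ROOT = Path(__file__).resolve().parents[1]


def main(seed: int = 0) -> None:
    out = ROOT / "results" / "data"
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    img, field, truth = pn.simulate_field(n_plaques=8, seed=rng)
    io.write_stain_image(out / "amyloid.tif", img)
    (out / "truth_plaques.json").write_text(json.dumps(truth, indent=2))

    # two plaque-enriched genes on a mostly homogeneous panel, mirroring the
    # composition of a targeted panel in which only a few probes respond
    specs = [
        pn.EnrichmentSpec("Cxcl10", 0.01, fold_inside=5.0, fold_adjacent=5.0),
        pn.EnrichmentSpec("Pdcd1", 0.01, fold_inside=5.0, fold_adjacent=5.0),
    ] + [
        pn.EnrichmentSpec(g, 0.01)
        for g in ("Actb", "Gapdh", "Tubb5", "Hexb", "Cst3", "P2ry12")
    ]
    table, ttruth = pn.make_transcripts(field, specs, seed=rng)
    io.write_transcripts(out / "transcripts.csv", table)
    ttruth["per_zone"].to_csv(out / "truth_transcripts.csv", index=False)

    panel = [f"g{i}" for i in range(20)]
    types = [
        pn.CellTypeSpec("tcell", tuple(panel[:5]), spatial_rule="plaque_adjacent"),
        pn.CellTypeSpec("microglia", tuple(panel[5:10])),
    ]
    cm, labels = pn.make_cells(types, 200, panel, field, seed=rng)
    io.write_cell_matrix(out / "matrix.mtx", out / "genes.tsv", out / "cells.tsv", cm)
    pd.DataFrame({"cell_id": cm.cells["cell_id"], "true_type": labels}).to_csv(
        out / "truth_cells.csv", index=False
    )

    dapi, tcell, iftruth = pn.make_if_images(50, 5, seed=rng)
    io.write_stain_image(out / "dapi.tif", dapi)
    io.write_stain_image(out / "tcell.tif", tcell)
    (out / "truth_if.json").write_text(json.dumps(iftruth, indent=2))

    print(f"window: {img.shape[0]} x {img.shape[1]} px at 1 µm/px")
    print(f"plaques planted: {len(truth['centers_px'])}")
    print(f"transcripts: {len(table)} across {table['gene'].nunique()} genes")
    print(f"cells: {cm.n_cells} over a {cm.n_genes}-marker panel")
    print(f"IF pair: {iftruth['n_nuclei']} nuclei, {iftruth['n_tcells']} T cells")
    print(f"written to {out}")


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    main(ap.parse_args().seed)
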