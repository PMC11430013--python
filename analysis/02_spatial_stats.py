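"""Spatial organization of Rubisco in the simulated population.

Reads the pose table from 01, computes per-carboxysome layer profiles
and the population summary, and reports the organization statistics the
cryoET analysis measures on real organelles: modal layer count, fraction
with 4-6 layers, Rubiscos per carboxysome, and neighbour distances.
"""

import json
from pathlib import Path

from carboxysome.io import read_poses, write_table
from carboxysome.pipeline import write_json
from carboxysome.spatial import summarize_population

OUT = Path("results")


def main() -> None:
    poses = read_poses(OUT / "poses.tsv")
    particles, per_carb, pop = summarize_population(poses)
    write_table(particles, OUT / "layer_profile.tsv")
    write_table(per_carb, OUT / "carboxysome_summary.tsv")
    write_json(pop, OUT / "population_summary.json")

    print(f"analysed {pop['n_carboxysomes']} carboxysomes "
          f"({int(per_carb['n_particles'].sum())} poses)")
    print(f"layer-count histogram: {pop['layer_count_histogram']} "
          f"(modal {pop['modal_layer_count']})")
    print(f"fraction with 4-6 layers: {pop['fraction_4_to_6_layers']:.1%}")
    print(f"Rubiscos per carboxysome: {pop['particle_count_mean']:.0f} "
          f"+/- {pop['particle_count_sd']:.0f}")
    print(f"neighbour distance (<= {pop['neighbour_cutoff_A']:.0f} A "
          f"pairs): {pop['neighbour_mean_A']:.1f} "
          f"+/- {pop['neighbour_sd_A']:.1f} A")
    print(f"first-nearest-neighbour distance: {pop['nn_mean_A']:.1f} "
          f"+/- {pop['nn_sd_A']:.1f} A")


if __name__ == "__main__":
    main()
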