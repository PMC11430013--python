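"""Generate the synthetic study inputs.

Simulates 200 carboxysomes at the default study conditions (diameters
Normal(169, 11.8) nm, 120 A concentric lattice, layer 4 calibrated to
174 Rubiscos, 15 A positional jitter, 10 deg orientation noise) plus two
QconCAT peptide tables built from the reference composition: one
noiseless and one at CV 0.2 with four replicates.
"""

from pathlib import Path

from carboxysome.config import (PoseSimConfig, QuantSimConfig, config_hash,
                                config_to_yaml)
from carboxysome.io import write_poses, write_quant, write_truth
from carboxysome.simulate import simulate_peptide_quant, simulate_population

OUT = Path("results")
SEED = 7


def main() -> None:
    pose_cfg = PoseSimConfig(seed=SEED)
    poses, truth = simulate_population(200, pose_cfg)
    h = config_hash(pose_cfg)
    write_poses(poses, OUT / "poses.tsv", h)
    write_truth(truth, OUT / "poses_truth.tsv", h)
    config_to_yaml(pose_cfg, OUT / "pose_config.yaml")
    print(f"simulated {truth['carboxysome_id'].nunique()} carboxysomes, "
          f"{len(poses)} Rubisco poses -> {OUT / 'poses.tsv'}")

    for tag, cv in (("noiseless", 0.0), ("cv20", 0.2)):
        quant_cfg = QuantSimConfig(noise_cv=cv, seed=SEED + 4)
        quant = simulate_peptide_quant(quant_cfg)
        write_quant(quant, OUT / f"peptide_quant_{tag}.csv",
                    config_hash(quant_cfg))
        print(f"wrote {len(quant)} peptide measurements "
              f"(CV {cv:.1f}) -> {OUT / f'peptide_quant_{tag}.csv'}")


if __name__ == "__main__":
    main()
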