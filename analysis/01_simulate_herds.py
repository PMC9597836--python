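#!/usr/bin/env python
"""Simulate the two study herds used by the downstream analysis scripts.

Two gene-dropped herds emulate the structure of the real data: a "goat"
herd with heavily incomplete parent recording (about a third of links
missing, so many animals have F_PED = 0 despite real autozygosity) and a
"sheep" herd with nearly complete pedigrees.  Both use sire overuse to
generate a spread of inbreeding.  Outputs (pedigree CSV, PLINK files,
truth track) go to results/sim/<species>/.
"""

from pathlib import Path

import pandas as pd

from rohbridge.plinkio import write_plink_binary, write_plink_text
from rohbridge.simulate import SimConfig, simulate_dataset

ROOT = Path(__file__).resolve().parents[1]
SEED = 1

CONFIGS = {
    "goat": SimConfig(n_founders=60, generations=8, sires_per_generation=5,
                      dams_per_generation=20, offspring_per_mating=2,
                      mating_scheme="sire-overuse", sire_overuse=3.0,
                      n_chromosomes=10, snps_per_chromosome=1000,
                      chromosome_length_mb=100, missing_rate=0.01,
                      mask_prob=0.25, seed=SEED),
    "sheep": SimConfig(n_founders=60, generations=8, sires_per_generation=5,
                       dams_per_generation=20, offspring_per_mating=2,
                       mating_scheme="sire-overuse", sire_overuse=3.0,
                       n_chromosomes=10, snps_per_chromosome=1000,
                       chromosome_length_mb=100, missing_rate=0.01,
                       mask_prob=0.08, seed=SEED + 1000),
}


def main():
    for species, cfg in CONFIGS.items():
        out = ROOT / "results" / "sim" / species
        out.mkdir(parents=True, exist_ok=True)
        bundle = simulate_dataset(cfg)
        ped = bundle["masked_pedigree"]
        rows = [{"id": a, "sire": ped.records[a].sire or "0",
                 "dam": ped.records[a].dam or "0",
                 "sex": ped.records[a].sex, "breed": species.upper()}
                for a in ped.order]
        pd.DataFrame(rows).to_csv(out / "pedigree.csv", index=False)
        full = bundle["pedigree"]
        pd.DataFrame([{"id": a, "sire": full.records[a].sire or "0",
                       "dam": full.records[a].dam or "0"}
                      for a in full.order]).to_csv(out / "pedigree_true.csv",
                                                   index=False)
        ds = bundle["dataset"]
        ds.species = species
        write_plink_text(ds, out / "herd.ped", out / "herd.map")
        write_plink_binary(ds, out / "herd.bed", out / "herd.bim",
                           out / "herd.fam")
        bundle["truth"].table.to_csv(out / "truth.tsv", sep="\t", index=False)
        masked_links = sum((ped.records[a].sire is None) +
                           (ped.records[a].dam is None) for a in ped.order)
        total = 2 * len(ped)
        print(f"{species}: {len(ped)} animals, {ds.n_snps} SNPs, "
              f"{masked_links}/{total} parent links unrecorded "
              f"-> {out.relative_to(ROOT)}")


if __name__ == "__main__":
    main()
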