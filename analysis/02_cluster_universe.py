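"""Cluster the chemical universe on Tanimoto distance with a Ward height cut.

Reads results/inputs/, computes the pairwise Tanimoto distance matrix over
universe fingerprints, cuts the Ward (ward.D2 dialect) tree at the default
height, and writes results/clusters.csv plus a size profile.  The profile's
singleton/doubleton counts are the diagnostics used to judge a cut height.
"""

import argparse
from pathlib import Path

from erconcord.clustering import cluster_size_profile, pairwise_distances, ward_cut
from erconcord.data_model import join_datasets, load_assay_aucs, load_chemicals, load_fingerprints, load_full_model
from erconcord.pipeline import load_config

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    args = parser.parse_args()
    cfg = load_config(overrides={"seed": args.seed})

    inp = ROOT / "results" / "inputs"
    chems = load_chemicals(inp / "chemicals.csv")
    fps = load_fingerprints(inp / "fingerprints.csv")
    aucs = load_assay_aucs(inp / "assay_aucs.csv")
    ref = load_full_model(inp / "full_model.csv")
    bundle = join_datasets(chems, fps, aucs, ref)

    univ_fps = fps.subset(bundle.universe_ids)
    dist = pairwise_distances(univ_fps)
    assign = ward_cut(dist, cfg["cut_height"], cfg["linkage_variant"])
    profile = cluster_size_profile(assign)

    out = ROOT / "results"
    assign.to_frame().to_csv(out / "clusters.csv", index=False)
    profile.sizes.reset_index().to_csv(out / "cluster_sizes.csv", index=False)
    print(
        f"{len(bundle.universe_ids)} universe chemicals -> {profile.n_clusters} clusters "
        f"(cut {cfg['cut_height']}, {cfg['linkage_variant']})"
    )
    print(f"singletons: {profile.n_singletons}, doubletons: {profile.n_doubletons}")


if __name__ == "__main__":
    main()
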