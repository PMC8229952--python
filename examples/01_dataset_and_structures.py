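"""Load the coumarin dataset and rebuild molecular structures.

The dataset encodes 40 assayed 2H-chromen-2-one derivatives (plus two
proposed follow-ups) as scaffold + substituent records with their measured
% inhibition of human DPP III at 10 uM.  Structures are reconstructed from
the substituent specification and embedded in 3D deterministically.
"""

from dpp3qsar import build_structure, embed_coordinates, load_paper_dataset

records = load_paper_dataset()
tested = [r for r in records if r.is_tested]
active = [r for r in tested if r.inhibition_pct is not None]
print(f"{len(tested)} tested compounds, {len(active)} active at 10 uM")

best = max(active, key=lambda r: r.inhibition_pct)
print(
    f"most potent: compound {best.compound_id} "
    f"({best.substituent_string()}), {best.inhibition_pct}% inhibition, "
    f"IC50 = {best.ic50_uM} uM"
)

graph = build_structure(best.substituents, name=str(best.compound_id))
print(f"formula {graph.molecular_formula()}; SMILES {graph.canonical_smiles()}")

struct = embed_coordinates(graph, seed=2021)
print(
    f"embedded {struct.coords.shape[0]} heavy atoms; max interatomic "
    f"distance {struct.distance_matrix().max():.2f} A"
)
# The distances feed the 3D-MoRSE descriptor; the same (molecule, seed)
# pair always regenerates identical coordinates.
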