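"""Profile the sequence context of detected errors.

Long-read assembly errors are not random: deletions in particular follow
homopolymers, because basecallers struggle to count run lengths.  This
example polishes a synthetic draft whose injected errors are homopolymer-
biased and tabulates, per error type, the upstream 4-mer and the length
of the homopolymer ending just before each error.
"""

from refpolish import PolishConfig, run_pipeline
from refpolish.profiling import (
    homopolymer_length_distribution,
    profile_table,
    upstream_kmer_profile,
)
from refpolish.simulate import SimulationSpec, default_error_mix, simulate_world

world = simulate_world(SimulationSpec(
    seed=2, genome_length=60_000, injected_errors=default_error_mix(40)))
result = run_pipeline(world.draft, world.ref_pileup, world.read_pileup,
                      config=PolishConfig())
final = [e for e in result.errors if e.applicable]

profile = upstream_kmer_profile(final, world.draft, k=4)
print(f"profiled {profile.total()} errors "
      f"({profile.excluded} too close to a contig start)")
print("top upstream 4-mers (error type, 4-mer, erroneous base, count):")
for row in profile_table(profile, top=3):
    print("  ", *row)

hist = homopolymer_length_distribution(final, world.draft)
print("upstream homopolymer length histogram per error type:")
for etype, counter in sorted(hist.items()):
    dist = "  ".join(f"{length}nt:{n}" for length, n in sorted(counter.items()))
    print(f"  {etype:<12} {dist}")
# Deletions cluster behind runs of >= 3 identical bases -- the signature
# the homopolymer-weighted site score exploits.
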