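# Methods

This note records the models, conventions and parameter choices behind
`spo11dock`, what the synthetic study conditions do and do not emulate,
and the numerical decisions a reader would need to reproduce or modify
the analyses.

## Structure model and radii

Structures are held as an ordered hierarchy (chains → residues → heavy
atoms) with author (deposited) numbering as the single numbering scheme,
because all residue landmarks used in the analyses (the catalytic Y135,
the metal triad E233/D288/D290, the 172|173 domain boundary, the Rec102
W91EEQ motif, Rec104 K43) are cited in author numbering.  Parsing and
writing of mmCIF/PDB go through gemmi; alternate locations are resolved
to the highest-occupancy conformer (ties by altloc label).  Hydrogens,
absent from the cryo-EM models, are ignored everywhere.

Van der Waals radii are a Bondi-like element table: C 1.70, N 1.55,
O 1.52, P 1.80, S 1.80, Mg 1.73 Å, default 1.70 Å.  The clash criterion
(below) absorbs small differences between published radius sets.

## Steric clashes

Two heavy atoms clash iff `r_A + r_B − d ≥ overlap_cutoff`, default
0.6 Å — the common interactive-modeling default; no published definition
of "clash" accompanies the figures being reproduced, so spacing analyses
are reported at 0.4 Å as well to show conclusions are insensitive to the
choice.  Counting uses a k-d tree but is exactly equivalent to the
all-pairs O(n²) count (asserted against a brute-force oracle in the
tests).

## Idealized B-form DNA and helical frames

The docking rail is a helical repeat of one coarse base-pair template
(per nucleotide: P, C1′, glycosidic N9/N1, ring anchors C2/C4), with
frame algebra `frame(i) = step^i`, `step` = twist about +z plus rise
along +z.  Defaults are twist 36.0°/bp (10 bp/turn) and rise 3.38 Å/bp;
both are configurable, and the spacing scan is additionally reported at
34.3°/bp (10.5 bp/turn) because the generic B-form builder behind the
published models is not specified.  The second strand is generated by
the base-pair dyad (180° about the local x axis), which makes the
strands antiparallel by construction and the 5′-terminal residue of each
strand phosphate-free.

Two deliberate idealizations:

* The template places every C1′–C1′ midpoint exactly on the helix axis.
  Real B-DNA base pairs are displaced ~1–2 Å off-axis; putting the
  midpoint on the axis makes the principal-component axis fit exact on
  built duplexes of any length (a fiber-accurate displacement would bias
  a straight-line fit on fragments of non-integral turn count).  Axis
  directions, docking frames and clash geometry are unaffected.
* The rail is never used for clash counting — only the docked complexes'
  own atoms are — so the coarse template costs nothing there.

## Base-pair detection

Watson–Crick partners are identified geometrically: candidate pairs
within 12.5 Å (C1′–C1′) are scored by the RMSD of a rigid fit of their
C1′/N/C2 anchors onto the canonical pair configuration, accepted below
1.5 Å, best score first, each partner used once.  Raw C1′–C1′ distance
alone cannot separate true partners from diagonal neighbours (the two
distances differ by < 0.1 Å at canonical geometry); the rigid-fit score
separates them by construction, and greedy exclusivity resolves the
remainder.  Overhangs and single-stranded regions fall out naturally as
residues with no acceptable partner.

## Superposition and geometric metrics

Superposition is the closed-form least-squares (Kabsch/SVD) fit with the
reflection branch folded back to a proper rotation; optimality is tested
against randomized brute force and cross-checked against SciPy's
`align_vectors`.  Whole-complex superposition defaults to shared protein
Cα atoms matched by (chain, seq_id), DNA excluded, because compared
structures carry different DNA ligands.

Rotation angles come from the trace formula (range [0°, 180°]).  Duplex
axes are principal-component lines through base-pair C1′–C1′ midpoints,
oriented 5′→3′ along the reference strand.  V-shape ("path") angles
between two duplexes are measured between the two oriented axes with
each axis pointing away from the junction — for break-end geometry the
5′-overhang strand's 5′→3′ direction already points away from the
junction, so a straight continuation scores 180° and the printed V
angles (130°, 150°) keep their meaning.  Axis offset is the minimal
line–line distance.

## Double-end docking and the spacing scan

A DNA-end-bound complex is docked onto an L-bp rail by Kabsch-fitting
the C1′/P atoms of its first four fully paired base pairs (counted from
the overhang end) onto the corresponding rail base pairs.  The far copy
is anchored at bp L−1 in the opposite strand sense, so decreasing L by
1 bp rotates it by one twist and advances it by one rise — the geometry
that couples break spacing to helical register.  Clashes are counted
between the two copies' protein moieties only (each copy's bound DNA and
the rail are excluded; configurable), matching the published convention
in which the collisions shown are between protein subunits.

Co-orientation means the relative azimuthal rotation of the two
placements about the rail axis (after removing the end-to-end flip) is
within 18° — half a base-pair twist, so each length classifies
unambiguously to its nearest helical register.  The headline outputs are
the smallest co-oriented clash-free L, the full list of qualifying
lengths (spaced one helical turn apart), and the center-to-center break
spacing L + 2 nt (the two-nucleotide overhangs flank the duplex).

## Pre-break dimer models

*Co-docked control.*  Two copies on one continuous rail in the break
register: the first 5′-overhang nucleotide of each copy one nucleotide
away from the partner's recessed 3′ end (a two-nucleotide 5′ stagger).
Clashes are reported protein-vs-protein and protein-vs-opposite-DNA; the
two DNA copies occupy complementary positions of one duplex and are not
counted against each other.

*Template-guided dimer.*  Each complex is split into two rigid bodies at
the catalytic subunit's WH|Toprim linker (172|173); the WH-side body
(with Rec102, Rec104 and the DNA — preserving the protein–DNA contacts)
and the Toprim-side body (with Ski8) are independently superposed onto
their cognate domains in each protomer of a dimer template via an
editable residue-mapping table (TSV: complex chain/seq ↔ template
chain/seq; Cα atoms, with C1′/P and then first-common-atom fallbacks so
synthetic templates work too).  Reported metrics: per-part RMSDs and
pair counts, the implied WH rotation `rotation_angle(T_N ∘ T_C⁻¹)`,
inter-protomer clash count, and the DNA geometry (V angle, axis offset,
end separation).  End separation pairs the innermost traced 5′ phosphate
of one copy's overhang strand with the partner's recessed-strand
3′-terminal O3′ (C1′ fallback on coarse DNA), averaged over the two
symmetric pairings; the printed "inferred 5′/3′ end positions" name no
atoms, so the atom choice is documented here and carries ~1 Å of
convention uncertainty.

## Contacts, SASA, interface areas

Contact detection is distance-only (no hydrogens in the models): N/O–N/O
hydrogen bonds ≤ 3.5 Å; Lys NZ / Arg NH1/NH2/NE to phosphate oxygens
≤ 4.0 Å (salt bridge); ion–O/N coordination ≤ 2.8 Å; vdW contact within
the radius sum + 0.4 Å.  Each close pair is classified once, most
specific kind first.

SASA is Shrake–Rupley with a deterministic Fibonacci sphere lattice
(default 960 points/atom, probe 1.4 Å) closed under inversion, so the
quadrature is RNG-free, reproducible, and exactly mirror-consistent
(symmetric configurations get identical per-atom areas).  Buried
interface area between bodies A and B is reported under both
conventions: the PISA-like half value (SASA(A)+SASA(B)−SASA(AB))/2 and
the unhalved total, because published interface figures rarely state
which was used; comparisons should pick one convention and keep it.

## Synthetic study conditions

The toy complex is the minimal object with the geometry the analyses
rely on: an idealized duplex (default 14 paired bp) whose reference
strand carries a two-nucleotide 5′ overhang (partner strand's 3′ end
recessed), plus a rigid excluded-volume envelope of carbon pseudo-atoms
(residue `ENV`, classified neither protein nor nucleotide, but included
in the protein-moiety clash counts).

* **Sphere envelope** (default radius 25 Å, centered on the axis 6 bp
  above the first paired base pair): sized to the real core complex's
  scale — a particle of a few tens of Å wrapped around ~half of a
  ~14-bp footprint — which places the analytic clash-free onset of the
  double-end scan at 29 bp and the minimal co-oriented clash-free length
  at 31 bp, the regime the real system occupies.  An axial chain of
  pseudo-atoms (spacing ≤ 1 Å, endpoints on the poles) makes the
  closest inter-envelope approach exactly `D − 2R` and guarantees that
  interpenetrating envelopes always register clashes, so the analytic
  onset formula is exact at every scan length.
* **Wrap envelope** (used for the dimer analyses; radius 12 Å, axial
  extent 30 Å, 540° left-handed arc) emulates the left-handed protein
  wrap, plus a disc of pseudo-atoms capping the break end — the feature
  that makes two B-form co-docked copies collide regardless of azimuth,
  as the real WH/Toprim domains do.
* **Synthetic dimer template**: two "protomers", each a copy of the toy
  complex whose two rigid bodies are placed by known transforms chosen
  to give a 45° WH rotation, a 150° DNA V angle and a 5 Å axis offset
  (the junction sits two steps below the 5′ ends, where the templated
  arrangement is clash-free while the co-docked control is not).
  Template-guided assembly must recover these numbers exactly, which is
  the package's end-to-end identity check.

What the toys do **not** emulate: real protein shape and flexibility,
sequence-dependent DNA geometry, the atomic detail of interfaces, or
cryo-EM coordinate error.  Passing synthetic tests therefore validates
the *machinery* (frames, docking, clash counting, alignment, metrics),
not the biological numbers; the real-structure acceptance tests exist
for the latter and require the deposited models
(`scripts/fetch_structures.py`).

## Numerical choices and degenerate inputs

* Kabsch requires ≥ 3 pairs; count mismatches and reflection branches
  are errors/corrections, never silent.
* Axis fitting requires ≥ 4 base pairs; parallel axes get a well-defined
  perpendicular offset.
* Near-identity rotations report axis +z by convention.
* The perturbed-pair generator emits a central 99% interval for the
  fitted RMSD from the first-order result that the fitted residual sum
  behaves as σ²·χ²(3n−6); the tests verify coverage by simulation.
* All randomness is `numpy.random.default_rng(seed)`-driven; fixtures
  are byte-identical for equal seeds.
* Scan and pipeline problem sizes (length range 20–45 bp, toy envelope
  ~150–380 atoms, 960 SASA points) were chosen so every analysis and
  the full oracle battery complete in seconds while leaving the clash
  onset well inside the scanned range.

## Known limitations

* The residue mapping between the catalytic subunit and the Top6A
  protomers of the deposited template (data/mappings/) ships as a
  documented, editable seed and must be completed by structure-guided
  Cα pairing against the deposited coordinates before the real
  template-guided dimer can be rebuilt; the published model states its
  alignments only as part RMSDs over 32 and 70 atom pairs.
* Helical axes are straight-line fits; strongly bent duplexes are out of
  scope (the bend is measured *between* two straight segments instead).
* H-bond detection is distance-only; no angular term, no waters.
* The PDB writer renames multi-character chain ids (logged mapping);
  mmCIF preserves them.
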