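External reference sequences (not redistributed with the package)
------------------------------------------------------------------

Two checks in tests/test_acceptance.py compare computed values against
published figures for real proteins.  The sequences themselves come from
public databases and are not bundled here; to run those checks, place a
protein FASTA at

    tests/data/reference/rc_reference_proteins.faa

containing six records with these exact ids:

    PufL_Chloroflexota_sp    PufL of Chloroflexota bacterium L.E.CH.39_1
    PufM_Chloroflexota_sp    PufM of Chloroflexota bacterium L.E.CH.39_1
                             (both encoded on NCBI contig JACAEO010000223)
    PufL_C_aurantiacus       PufL of Chloroflexus aurantiacus
    PufM_C_aurantiacus       PufM of Chloroflexus aurantiacus
    PufL_R_castenholzii      PufL of Roseiflexus castenholzii
    PufM_R_castenholzii      PufM of Roseiflexus castenholzii

Without this file the two tests fail with a pointer to this note; every
other test in the suite is self-contained.
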