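>sp|P63316|TNNC1_HUMAN Troponin C, slow skeletal and cardiac muscles
MDDIYKAAVEQLTEEQKNEFKAAFDIFVLGAEDGCISTKELGKVMRMLGQNPTPEELQEM
IDEVDEDGSGTVDFDEFLVMMVRCMKDDSKGKSEEELSDLFRMFDKNADGYIDLDELKIM
LQATGETITEDDIEELMKDGDKNNDGRIDYDEFLEFMKGVE
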