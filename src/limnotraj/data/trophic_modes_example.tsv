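class	mode
Cryptophyceae	mixotroph
Chrysophyceae	mixotroph
Dinophyceae	mixotroph
Haptophyta_Clade_1	mixotroph
Chlorophyceae	phototroph
Trebouxiophyceae	phototroph
Bacillariophyceae	phototroph
Mediophyceae	phototroph
Eustigmatophyceae	phototroph
Zygnemophyceae	phototroph
Spirotrichea	phagotroph
Oligohymenophorea	phagotroph
Litostomatea	phagotroph
Chrysophyceae_Clade_C	phagotroph
Bicoecea	phagotroph
Choanoflagellatea	phagotroph
Katablepharidaceae	phagotroph
Cercozoa_Clade_A	phagotroph
Chytridiomycetes	parasite
Perkinsea	parasite
Syndiniales	parasite
Oomycota	parasite
Ichthyosporea	parasite
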