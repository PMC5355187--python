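# Synthetic 12-species focal-area flora (toy fixture; constructed, not field data)
species_id,large_seeded_reliant
Astrocaryum aculeatissimum,true
Sterculia chicha,true
Joannesia princeps,true
Lecythis pisonis,true
Syagrus romanzoffiana,true
Eugenia uniflora,false
Psidium cattleianum,false
Cecropia glaziovii,false
Ficus insipida,false
Miconia cinnamomifolia,false
Guarea guidonia,false
Inga edulis,false
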