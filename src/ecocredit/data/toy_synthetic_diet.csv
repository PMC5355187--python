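# Synthetic diet/interaction reference for a scatter-hoarding rodent (toy fixture; constructed, not literature data)
animal_id,plant_id,source
agouti,Astrocaryum aculeatissimum,toy
agouti,Sterculia chicha,toy
agouti,Joannesia princeps,toy
agouti,Lecythis pisonis,toy
agouti,Syagrus romanzoffiana,toy
agouti,Inga edulis,toy
agouti,Guarea guidonia,toy
agouti,Ficus insipida,toy
agouti,Bertholletia excelsa,toy
agouti,Attalea humilis,toy
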