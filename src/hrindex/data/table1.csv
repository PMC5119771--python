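study_id,first_author,year,arm,n,age_mean,male_pct,category,protocol,rail_support,hr_rest,hr_max,vo2peak,vo2_units,vo2_source
bard2006,Bard,2006,measured,355,51,72,CHF,ramp,not_stated,,,,,
diller2006,Diller,2006,measured,727,33,52,ACHD,MB,not_stated,,,,,
dressendorfer1993,Dressendorfer,1993,measured,182,57,100,CAD,MB,not_permitted,,,,,
elmariah2006,Elmariah,2006,measured,594,52,72,CHF,ramp,not_stated,,,,,
harrington1997,Harrington,1997,measured,131,59,100,"CHF, H",MB,not_stated,,,,,
ingle2007,Ingle,2007,measured,394,65,74,CHF,MB,not_stated,,,,,
jorde2008,Jorde,2008,measured,278,52,77,CHF,Na,not_stated,,,,,
kohrt1991,Kohrt,1991,measured,110,64,50,H,"B,O",not_stated,,,,,
kubrychtova2009,Kubrychtova,2009,measured,712,56,72,CHF,O,not_stated,,,,,
lanier2012,Lanier,2012,measured,320,52,75,CHF,Na,not_stated,,,,,
mcdonough1970,McDonough,1970,measured,144,51,100,H,B,not_stated,,,,,
nes2012,Nes,2012,measured,4631,48,49,H,ramp,not_stated,,,,,
oliveira2009,Oliveira,2009,measured,948,57,100,"CPD, H",ramp,discouraged,,,,,
osada1998,Osada,1998,measured,154,52,75,CHF,"MB, MNa",not_stated,,,,,
peterson2003,Peterson,2003,measured,369,51,72,CHF,O,not_stated,,,,,
robbins1999,Robbins,1999,measured,487,52,71,"CHF, H",Na,not_stated,,,,,
schalcher2003,Schalcher,2003,measured,146,52,88,CHF,ramp,not_stated,,,,,
stolker2006,Stolker,2006,measured,221,49,68,CHF,O,not_stated,,,,,
williams2001,Williams,2001,measured,219,56,76,CHF,"B, MB",not_stated,,,,,
witte2006,Witte,2006,measured,355,66,68,"CHF, H",MB,not_stated,,,,,
adabag2008,Adabag,2008,predicted,12555,46,100,CAD-absent,B,not_stated,,,,,
aijaz2008,Aijaz,2008,predicted,10897,54,75,"CVD, CVD-absent",B,not_stated,,,,,
arruda_olson2002,Arruda-Olson,2002,predicted,5798,62,57,"CAD, CAD-suspected","B, MB, Na",not_stated,,,,,
carnethon2003,Carnethon,2003,predicted,4487,25,45,H,MBa,not_stated,,,,,
cheng2003,Cheng,2003,predicted,2333,49,100,DM,MBa,not_stated,,,,,
elhendy2001,Elhendy,2001,predicted,1618,55,35,CAD-suspected,"B, MB, Na",not_stated,,,,,
gulati2010,Gulati,2010,predicted,5437,52,0,CAD-absent,B,light_support,,,,,
kim2007,Kim,2007,predicted,22275,51,59,CVD-absent,"B, MB, O",not_permitted,,,,,
kokkinos2009,Kokkinos,2009,predicted,4631,61,100,HT,"B, ramp",discouraged,,,,,
lai2004,Lai,2004,predicted,5625,59,100,CVD-absent,"ramp, O",not_stated,,,,,
lauer1999,Lauer,1999,predicted,2953,58,64,"CVD-absent, CVD-suspected","B, MB",not_permitted,,,,,
lipinski2005,Lipinski,2005,predicted,1914,52,100,"CAD, CHF, CAD-absent","ramp, O",not_stated,,,,,
mahenthiran2005,Mahenthiran,2005,predicted,1268,60,52,"CAD, CAD-absent",B,not_stated,,,,,
mcauley2007,McAuley,2007,predicted,6876,58,97,"CAD, CAD-absent",ramp,discouraged,,,,,
mora2003,Mora,2003,predicted,2985,47,0,CAD-absent,B,not_stated,,,,,
morrow1993,Morrow,1993,predicted,2546,59,100,"CAD-absent, CAD, CHF","ramp, O",not_stated,,,,,
myers2002,Myers,2002,predicted,6213,59,100,"CAD, CAD-absent",ramp,discouraged,,,,,
negishi2013,Negishi,2013,predicted,914,56,56,DM,"B, MB",not_permitted,,,,,
peteiro2010,Peteiro,2010,predicted,2947,62,61,"CAD, CAD-suspected","B, MB, Na",not_stated,,,,,
shaw2011,Shaw,2011,predicted,772,63,0,CAD-suspected,"B, MB",not_stated,,,,,
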