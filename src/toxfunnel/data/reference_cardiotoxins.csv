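name,predicted_cardiotoxicity,aux_flagged
5-Fluorouracil,Yes,0
Aconitine,Yes,0
Amifostine,Yes,0
Amphetamine,Yes,0
Atropine,Yes,0
Chloroprocaine,Yes,0
Clenbuterol,Yes,0
Clonidine,Yes,0
Cocaine,Yes,0
Digoxin,Yes,0
Dobutamine,Yes,0
Doxazosin,Yes,0
Doxorubicin,Yes,0
Grayanotoxin III 6.14 diacetate,Yes,1
Ibuprofen,Yes,0
Ibutilide,Yes,0
Isoprenaline,Yes,0
Lapatinib,Yes,0
Levosimendan,Yes,0
Lidocain,Yes,0
Malathion,No,1
Metamphetamine,Yes,0
Methyldopa,No,1
Methyltestosterone,Yes,0
Metoprolol,Yes,0
Milrinone,No,0
Nortrpytiline,Yes,0
Paclitaxel,Yes,0
Phenylephrine,Yes,0
Prednisone,Yes,0
Reserpine,Yes,0
Ritodrine,Yes,0
Rofecoxib,Yes,0
Salbutamol,Yes,0
Sildenafil,Yes,0
Sorafenib,No,1
Theohylline,Yes,0
Verapamil,Yes,0
Yohimbine,Yes,0
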