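code,binomial,family,phyllotaxis,life_form,leaf_type,venation_class
Ame,Amphicarpaea bracteata,Fabaceae,alternate,herbaceous,ternate,basal actinodromous
Atg,Acer ginnala,Sapindaceae,opposite,woody,simple,basal actinodromous
Auc,Aucuba japonica,Aucubaceae,opposite,woody,simple,semicraspedodromous
Bid,Bidens sp.,Asteraceae,opposite,herbaceous,pinnate,craspedodromous
Bpt,Betula platyphylla,Betulaceae,alternate,woody,simple,craspedodromous
Cay,Cayratia japonica,Vitaceae,alternate,herbaceous,palmate,craspedodromous
Ces,Cerasus sargentii,Rosaceae,alternate,woody,simple,semicraspedodromous
Coc,Cornus controversa,Cornaceae,alternate,woody,simple,eucamptodromous
Cpa,Chenopodium album,Amaranthaceae,alternate,herbaceous,simple,suprabasal actinodromous
Cyr,Cynanchum rostellatum,Apocynaceae,opposite,herbaceous,simple,semicraspedodromous
Elc,Eleutherococcus senticosus,Araliaceae,alternate,woody,palmate,semicraspedodromous
Eua,Euonymus alatus,Celastraceae,opposite,woody,simple,semicraspedodromous
Fas,Fallopia sachalinensis,Polygonaceae,alternate,herbaceous,simple,semicraspedodromous
Fms,Fraxinus mandshurica,Oleaceae,opposite,woody,pinnate,semicraspedodromous
Hyp,Hydrangea paniculata,Hydrangeaceae,opposite,woody,simple,eucamptodromous
Jms,Juglans mandshurica,Juglandaceae,alternate,woody,pinnate,craspedodromous
Jpc,Justicia procumbens,Acanthaceae,opposite,herbaceous,simple,eucamptodromous
Lgo,Ligustrum obtusifolium,Oleaceae,opposite,woody,simple,brochidodromous
Lon,Lonicera japonica,Caprifoliaceae,opposite,woody,simple,semicraspedodromous
Mkb,Magnolia kobus,Magnoliaceae,alternate,woody,simple,craspedodromous
Oeb,Oenothera biennis,Onagraceae,alternate,herbaceous,simple,semicraspedodromous
Pas,Paederia foetida,Rubiaceae,opposite,herbaceous,simple,semicraspedodromous
Piq,Picrasma quassioides,Simaroubaceae,alternate,woody,pinnate,semicraspedodromous
Pps,Populus suaveolens,Salicaceae,alternate,woody,simple,craspedodromous
Qmc,Quercus crispula,Fagaceae,alternate,woody,simple,craspedodromous
Rhd,Rhododendron brachycarpum,Ericaceae,alternate,woody,simple,craspedodromous
Scs,Scutellaria strigillosa,Lamiaceae,opposite,herbaceous,simple,semicraspedodromous
Sol,Solanum sp.,Solanaceae,alternate,herbaceous,simple,semicraspedodromous
Sym,Symphytum officinale,Boraginaceae,alternate,herbaceous,simple,reticulodromous
Udj,Ulmus davidiana var. japonica,Ulmaceae,alternate,woody,simple,craspedodromous
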