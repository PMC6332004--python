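compound_id,name,formula,mw,source
1,umbelliferone,C9H6O3,162.14,formula
2,osthol,C15H16O3,244.29,formula
3,scopoletin,C10H8O4,192.17,formula
4,peucedanol,C14H16O5,264.27,formula
5,ulopterol,C15H18O5,278.30,formula
6,angepubebisin,C24H20O7,420.41,assumed_formula
7,psoralen,C11H6O3,186.16,formula
8,xanthotoxin,C12H8O4,216.19,formula
9,bergapten,C12H8O4,216.19,formula
10,isoimperatorin,C16H14O4,270.28,formula
11,columbianadin,C19H20O5,328.36,formula
12,columbianetin acetate,C16H16O5,288.30,formula
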