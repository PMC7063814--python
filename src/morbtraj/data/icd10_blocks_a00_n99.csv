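block_id,chapter,first_code,last_code,label
0,I,A00,A09,Intestinal infectious diseases
1,I,A15,A19,Tuberculosis
2,I,A20,A28,Certain zoonotic bacterial diseases
3,I,A30,A49,Other bacterial diseases
4,I,A50,A64,Infections with a predominantly sexual mode of transmission
5,I,A65,A69,Other spirochaetal diseases
6,I,A70,A74,Other diseases caused by chlamydiae
7,I,A75,A79,Rickettsioses
8,I,A80,A89,Viral infections of the central nervous system
9,I,A90,A99,Arthropod-borne viral fevers and viral haemorrhagic fevers
10,I,B00,B09,Viral infections characterized by skin and mucous membrane lesions
11,I,B15,B19,Viral hepatitis
12,I,B20,B24,Human immunodeficiency virus disease
13,I,B25,B34,Other viral diseases
14,I,B35,B49,Mycoses
15,I,B50,B64,Protozoal diseases
16,I,B65,B83,Helminthiases
17,I,B85,B89,Pediculosis acariasis and other infestations
18,I,B90,B94,Sequelae of infectious and parasitic diseases
19,I,B95,B98,Bacterial viral and other infectious agents
20,I,B99,B99,Other infectious diseases
21,II,C00,C97,Malignant neoplasms
22,II,D00,D09,In situ neoplasms
23,II,D10,D36,Benign neoplasms
24,II,D37,D48,Neoplasms of uncertain or unknown behaviour
25,III,D50,D53,Nutritional anaemias
26,III,D55,D59,Haemolytic anaemias
27,III,D60,D64,Aplastic and other anaemias
28,III,D65,D69,Coagulation defects purpura and other haemorrhagic conditions
29,III,D70,D77,Other diseases of blood and blood-forming organs
30,III,D80,D89,Certain disorders involving the immune mechanism
31,IV,E00,E07,Disorders of thyroid gland
32,IV,E10,E14,Diabetes mellitus
33,IV,E15,E16,Other disorders of glucose regulation and pancreatic internal secretion
34,IV,E20,E35,Disorders of other endocrine glands
35,IV,E40,E46,Malnutrition
36,IV,E50,E64,Other nutritional deficiencies
37,IV,E65,E68,Obesity and other hyperalimentation
38,IV,E70,E90,Metabolic disorders
39,V,F00,F09,Organic including symptomatic mental disorders
40,V,F10,F19,Mental and behavioural disorders due to psychoactive substance use
41,V,F20,F29,Schizophrenia schizotypal and delusional disorders
42,V,F30,F39,Mood affective disorders
43,V,F40,F48,Neurotic stress-related and somatoform disorders
44,V,F50,F59,Behavioural syndromes associated with physiological disturbances
45,V,F60,F69,Disorders of adult personality and behaviour
46,V,F70,F79,Mental retardation
47,V,F80,F89,Disorders of psychological development
48,V,F90,F98,Behavioural and emotional disorders with onset in childhood
49,V,F99,F99,Unspecified mental disorder
50,VI,G00,G09,Inflammatory diseases of the central nervous system
51,VI,G10,G14,Systemic atrophies primarily affecting the central nervous system
52,VI,G20,G26,Extrapyramidal and movement disorders
53,VI,G30,G32,Other degenerative diseases of the nervous system
54,VI,G35,G37,Demyelinating diseases of the central nervous system
55,VI,G40,G47,Episodic and paroxysmal disorders
56,VI,G50,G59,Nerve nerve root and plexus disorders
57,VI,G60,G64,Polyneuropathies and other disorders of the peripheral nervous system
58,VI,G70,G73,Diseases of myoneural junction and muscle
59,VI,G80,G83,Cerebral palsy and other paralytic syndromes
60,VI,G90,G99,Other disorders of the nervous system
61,VII,H00,H06,Disorders of eyelid lacrimal system and orbit
62,VII,H10,H13,Disorders of conjunctiva
63,VII,H15,H22,Disorders of sclera cornea iris and ciliary body
64,VII,H25,H28,Disorders of lens
65,VII,H30,H36,Disorders of choroid and retina
66,VII,H40,H42,Glaucoma
67,VII,H43,H45,Disorders of vitreous body and globe
68,VII,H46,H48,Disorders of optic nerve and visual pathways
69,VII,H49,H52,Disorders of ocular muscles binocular movement accommodation and refraction
70,VII,H53,H54,Visual disturbances and blindness
71,VII,H55,H59,Other disorders of eye and adnexa
72,VIII,H60,H62,Diseases of external ear
73,VIII,H65,H75,Diseases of middle ear and mastoid
74,VIII,H80,H83,Diseases of inner ear
75,VIII,H90,H95,Other disorders of ear
76,IX,I00,I02,Acute rheumatic fever
77,IX,I05,I09,Chronic rheumatic heart diseases
78,IX,I10,I15,Hypertensive diseases
79,IX,I20,I25,Ischaemic heart diseases
80,IX,I26,I28,Pulmonary heart disease and diseases of pulmonary circulation
81,IX,I30,I52,Other forms of heart disease
82,IX,I60,I69,Cerebrovascular diseases
83,IX,I70,I79,Diseases of arteries arterioles and capillaries
84,IX,I80,I89,Diseases of veins lymphatic vessels and lymph nodes
85,IX,I95,I99,Other and unspecified disorders of the circulatory system
86,X,J00,J06,Acute upper respiratory infections
87,X,J09,J18,Influenza and pneumonia
88,X,J20,J22,Other acute lower respiratory infections
89,X,J30,J39,Other diseases of upper respiratory tract
90,X,J40,J47,Chronic lower respiratory diseases
91,X,J60,J70,Lung diseases due to external agents
92,X,J80,J84,Other respiratory diseases principally affecting the interstitium
93,X,J85,J86,Suppurative and necrotic conditions of lower respiratory tract
94,X,J90,J94,Other diseases of pleura
95,X,J95,J99,Other diseases of the respiratory system
96,XI,K00,K14,Diseases of oral cavity salivary glands and jaws
97,XI,K20,K31,Diseases of oesophagus stomach and duodenum
98,XI,K35,K38,Diseases of appendix
99,XI,K40,K46,Hernia
100,XI,K50,K52,Noninfective enteritis and colitis
101,XI,K55,K64,Other diseases of intestines
102,XI,K65,K67,Diseases of peritoneum
103,XI,K70,K77,Diseases of liver
104,XI,K80,K87,Disorders of gallbladder biliary tract and pancreas
105,XI,K90,K93,Other diseases of the digestive system
106,XII,L00,L08,Infections of the skin and subcutaneous tissue
107,XII,L10,L14,Bullous disorders
108,XII,L20,L30,Dermatitis and eczema
109,XII,L40,L45,Papulosquamous disorders
110,XII,L50,L54,Urticaria and erythema
111,XII,L55,L59,Radiation-related disorders of the skin and subcutaneous tissue
112,XII,L60,L75,Disorders of skin appendages
113,XII,L80,L99,Other disorders of the skin and subcutaneous tissue
114,XIII,M00,M25,Arthropathies
115,XIII,M30,M36,Systemic connective tissue disorders
116,XIII,M40,M54,Dorsopathies
117,XIII,M60,M79,Soft tissue disorders
118,XIII,M80,M94,Osteopathies and chondropathies
119,XIII,M95,M99,Other disorders of the musculoskeletal system and connective tissue
120,XIV,N00,N08,Glomerular diseases
121,XIV,N10,N16,Renal tubulo-interstitial diseases
122,XIV,N17,N19,Renal failure
123,XIV,N20,N23,Urolithiasis
124,XIV,N25,N29,Other disorders of kidney and ureter
125,XIV,N30,N39,Other diseases of urinary system
126,XIV,N40,N51,Diseases of male genital organs
127,XIV,N60,N64,Disorders of breast
128,XIV,N70,N77,Inflammatory diseases of female pelvic organs
129,XIV,N80,N98,Noninflammatory disorders of female genital tract
130,XIV,N99,N99,Other disorders of the genitourinary system
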